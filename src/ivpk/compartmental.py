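"""Two- and three-compartment IV-bolus models.

The plasma concentration after an instantaneous intravenous dose into the
central compartment of a mammillary model with first-order transfer is a
sum of decaying exponentials

    C(t) = A e^(-alpha t) + B e^(-beta t) [+ C e^(-gamma t)],

whose exponents are the negated eigenvalues of the compartmental rate
matrix and whose coefficients are the partial-fraction residues of the
central-compartment solution with C(0) = dose / V1. This module provides
the macro <-> micro conversions in both directions, weighted nonlinear
fitting of the macro form to observed profiles (1/y^2 weights, i.e.
relative residuals), and the secondary descriptors (volumes, clearance,
half-lives, depth, capacity, central fraction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import DerivedPK, FitDiagnostics, MacroParams, MicroParams, SubjectProfile

__all__ = [
    "predict_concentration",
    "rate_matrix",
    "micro_to_macro",
    "macro_to_micro",
    "fit_iv_bolus",
    "derived_parameters",
    "population_summary",
    "DegeneracyError",
    "ConvergenceError",
]

LN2 = math.log(2.0)


class DegeneracyError(ValueError):
    """Raised when the rate matrix has repeated (or non-real) eigenvalues."""


class ConvergenceError(RuntimeError):
    """Raised when no start of the weighted fit converges."""


def predict_concentration(macro: MacroParams, t) -> np.ndarray | float:
    """Evaluate C(t) = sum_i coef_i * exp(-exp_i * t) at time(s) ``t`` (h)."""
    t_arr = np.asarray(t, dtype=float)
    coefs = np.asarray(macro.coefficients)
    exps = np.asarray(macro.exponents)
    c = coefs @ np.exp(-np.outer(exps, np.atleast_1d(t_arr)))
    return float(c[0]) if t_arr.ndim == 0 else c


def rate_matrix(micro: MicroParams) -> np.ndarray:
    """First-order rate matrix K such that d(amounts)/dt = K @ amounts."""
    if micro.k13 is not None:
        return np.array(
            [
                [-(micro.k10 + micro.k12 + micro.k13), micro.k21, micro.k31],
                [micro.k12, -micro.k21, 0.0],
                [micro.k13, 0.0, -micro.k31],
            ]
        )
    return np.array(
        [
            [-(micro.k10 + micro.k12), micro.k21],
            [micro.k12, -micro.k21],
        ]
    )


def micro_to_macro(micro: MicroParams, dose: float) -> MacroParams:
    """Convert rate constants to the sum-of-exponentials (macro) form.

    Exponents are the negated eigenvalues of the rate matrix; coefficients
    come from the eigen-decomposition of the central-compartment solution
    with initial amount ``dose`` in compartment 1. Terms with (numerically)
    zero residue — e.g. the k12 = k21 = 0 degenerate one-compartment case —
    are dropped.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    K = rate_matrix(micro)
    eigvals, P = np.linalg.eig(K)
    if np.max(np.abs(eigvals.imag)) > 1e-9 * max(1.0, np.max(np.abs(eigvals.real))):
        raise DegeneracyError("rate matrix has complex eigenvalues")
    eigvals = eigvals.real
    scale = np.max(np.abs(eigvals))
    gaps = np.abs(np.subtract.outer(eigvals, eigvals))
    np.fill_diagonal(gaps, np.inf)
    if gaps.min() < 1e-10 * scale:
        raise DegeneracyError("repeated eigenvalues: model is degenerate")
    x0 = np.zeros(K.shape[0])
    x0[0] = dose
    y = np.linalg.solve(P, x0)
    residues = P.real[0, :] * y.real / micro.V1  # ng/mL per exponential term
    c0 = dose / micro.V1
    keep = np.abs(residues) > 1e-10 * c0
    coefs = residues[keep]
    exps = -eigvals[keep]
    if np.any(exps <= 0) or np.any(coefs <= 0):
        raise DegeneracyError("non-positive exponent or coefficient in macro form")
    return MacroParams(tuple(coefs), tuple(exps))


def macro_to_micro(macro: MacroParams, dose: float) -> MicroParams:
    """Convert macro constants to mammillary rate constants and V1.

    Two compartments:
        V1 = dose/(A+B);  k21 = (A beta + B alpha)/(A+B);
        k10 = alpha beta / k21;  k12 = alpha + beta - k10 - k21.
    Three compartments use the analogous polynomial relations between the
    characteristic polynomial of the rate matrix and the transfer-function
    zeros (which are -k21 and -k31).
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    c0 = macro.c0
    V1 = dose / c0
    n = macro.n_compartments
    if n == 1:
        return MicroParams(k10=macro.exponents[0], k12=0.0, k21=0.0, V1=V1)
    if n == 2:
        (A, B), (alpha, beta) = macro.coefficients, macro.exponents
        k21 = (A * beta + B * alpha) / c0
        k10 = alpha * beta / k21
        k12 = alpha + beta - k10 - k21
        _check_rates(k10=k10, k12=k12, k21=k21)
        return MicroParams(k10=k10, k12=k12, k21=k21, V1=V1)
    (A, B, C), (alpha, beta, gamma) = macro.coefficients, macro.exponents
    fA, fB, fC = A / c0, B / c0, C / c0
    # zeros of the central-compartment transfer function: x^2 - b2 x + b1
    b2 = fA * (beta + gamma) + fB * (alpha + gamma) + fC * (alpha + beta)
    b1 = fA * beta * gamma + fB * alpha * gamma + fC * alpha * beta
    disc = b2 * b2 - 4.0 * b1
    if disc <= 0:
        raise DegeneracyError("macro constants give no real peripheral exit rates")
    root = math.sqrt(disc)
    k21 = (b2 + root) / 2.0
    k31 = (b2 - root) / 2.0
    a2 = alpha + beta + gamma
    a1 = alpha * beta + alpha * gamma + beta * gamma
    a0 = alpha * beta * gamma
    k10 = a0 / (k21 * k31)
    s = a2 - k10 - k21 - k31  # = k12 + k13
    m = a1 - k10 * (k21 + k31) - k21 * k31  # = k12 k31 + k13 k21
    k12 = (m - s * k21) / (k31 - k21)
    k13 = s - k12
    _check_rates(k10=k10, k12=k12, k21=k21, k13=k13, k31=k31)
    return MicroParams(k10=k10, k12=k12, k21=k21, V1=V1, k13=k13, k31=k31)


def _check_rates(**rates: float) -> None:
    bad = {name: val for name, val in rates.items() if val <= 0}
    if bad:
        raise ValueError(f"macro constants imply non-positive rate(s): {bad}")


# ---------------------------------------------------------------------------
# Weighted nonlinear fitting


def _strip_exponentials(t: np.ndarray, c: np.ndarray, n_terms: int) -> np.ndarray:
    """Curve-stripping (exponential peeling) initial estimates.

    Fits the terminal log-linear segment, subtracts it, and repeats on the
    residual for faster phases. Returns log-parameters
    [log coefs (fast..slow), log exponents (fast..slow)].
    """
    remaining = c.astype(float).copy()
    coefs: list[float] = []
    exps: list[float] = []
    t_span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    for term in range(n_terms):
        last = term == n_terms - 1
        pos = remaining > 0
        if pos.sum() >= 2:
            tt, cc = t[pos], remaining[pos]
            if not last:
                m = max(3, len(tt) // n_terms)
                tt, cc = tt[-m:], cc[-m:]
            slope, intercept = np.polyfit(tt, np.log(cc), 1)
            lam = max(-slope, 1e-3 / t_span)
            coef = math.exp(intercept)
        else:  # peeling failed; fall back to a spread heuristic
            lam = (term + 1) / t_span
            coef = max(c[0] / n_terms, 1e-6)
        # peel from the slow end: store slow-first, reverse at the end
        coefs.append(coef)
        exps.append(lam)
        remaining = remaining - coef * np.exp(-lam * t)
    coefs_arr = np.array(coefs[::-1])
    exps_arr = np.array(exps[::-1])
    # enforce strictly decreasing exponents for a sane start
    for i in range(1, n_terms):
        if exps_arr[i] >= exps_arr[i - 1]:
            exps_arr[i] = exps_arr[i - 1] / (3.0 + i)
    return np.log(np.concatenate([coefs_arr, exps_arr]))


def _relative_residuals(theta: np.ndarray, t: np.ndarray, obs: np.ndarray, k: int):
    theta = np.clip(theta, -35.0, 35.0)  # keep exp() finite far from the optimum
    coefs = np.exp(theta[:k])
    lams = np.exp(theta[k:])
    pred = coefs @ np.exp(-np.outer(lams, t))
    return (obs - pred) / obs  # 1/y_obs^2 weighting


def fit_iv_bolus(
    profile: SubjectProfile,
    n_compartments: int = 2,
    *,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[MacroParams, FitDiagnostics]:
    """Fit a 2- or 3-compartment IV-bolus model by weighted least squares.

    Minimises WRSS = sum_i w_i (C_obs,i - C_pred,i)^2 with w_i = 1/C_obs,i^2,
    which down-weights the high early concentrations so the terminal phase
    is estimated as well as the peak. Parameters are optimised on the log
    scale (positivity), starting from curve-stripping estimates plus
    ``n_restarts`` jittered restarts; the best WRSS wins. Exponents of the
    returned macro parameters are sorted fastest-first.
    """
    if n_compartments not in (2, 3):
        raise ValueError("n_compartments must be 2 or 3")
    t, obs = profile.quantifiable()
    k = n_compartments
    n_params = 2 * k
    if len(t) < n_params + 1:
        raise ValueError(
            f"need at least {n_params + 1} quantifiable points for {k} compartments"
        )
    theta0 = _strip_exponentials(t, obs, k)
    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        theta0 + rng.normal(0.0, 0.3, size=theta0.size) for _ in range(n_restarts)
    ]
    best = None
    for start in starts:
        try:
            res = least_squares(
                _relative_residuals, start, args=(t, obs, k), method="lm", xtol=1e-12
            )
        except Exception:
            continue
        wrss = float(res.cost * 2.0)
        if best is None or wrss < best[1]:
            best = (res, wrss)
    if best is None:
        raise ConvergenceError("all fitting starts failed")
    res, wrss = best
    coefs = np.exp(res.x[:k])
    lams = np.exp(res.x[k:])
    order = np.argsort(lams)[::-1]
    coefs, lams = coefs[order], lams[order]
    if np.any(lams[:-1] / lams[1:] < 1.1):
        warnings.warn(
            "fitted exponents are nearly equal; the model is over-parameterised — "
            f"consider refitting with {k - 1} compartment(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    macro = MacroParams(tuple(coefs), tuple(lams))
    w = 1.0 / obs**2
    wmean = np.sum(w * obs) / np.sum(w)
    wtss = float(np.sum(w * (obs - wmean) ** 2))
    n = len(obs)
    diag = FitDiagnostics(
        wrss=wrss,
        df=n - n_params,
        aic=_aic(wrss, n, n_params),
        r_squared=max(0.0, 1.0 - wrss / wtss),
        n_params=n_params,
        n_points=n,
    )
    return macro, diag


def _aic(wrss: float, n: int, p: int) -> float:
    if wrss <= 0:
        return float("-inf")
    return n * math.log(wrss / n) + 2 * p


# ---------------------------------------------------------------------------
# Derived parameters and population summaries


def derived_parameters(micro: MicroParams, macro: MacroParams) -> DerivedPK:
    """Secondary disposition descriptors from a micro/macro pair.

    Volumes, clearance, depth and capacity come from the rate constants:
    Vss = V1 (1 + k12/k21 [+ k13/k31]), Cl = V1 k10, depth = k10/k12,
    capacity = k12/k21. Half-lives and the central fraction come from the
    exponents: t_half = ln 2 / exponent (fastest = distribution, slowest =
    terminal elimination) and fc = beta/k10 with beta the slowest exponent.
    """
    if micro.k12 == 0 or micro.k21 == 0:
        raise ValueError("depth and capacity require k12, k21 > 0")
    vss = micro.V1 * (1.0 + micro.k12 / micro.k21)
    if micro.k13 is not None:
        vss += micro.V1 * micro.k13 / micro.k31
    exps = macro.exponents  # sorted fastest first
    return DerivedPK(
        vss=vss,
        cl=micro.V1 * micro.k10,
        t_half_dist=LN2 / exps[0],
        t_half_elim=LN2 / exps[-1],
        depth=micro.k10 / micro.k12,
        capacity=micro.k12 / micro.k21,
        fc=exps[-1] / micro.k10,
    )


def population_summary(per_subject: list) -> pd.DataFrame:
    """Arithmetic mean and sample SD of each parameter across subjects.

    Each subject is fitted individually and summarised afterwards (no
    pooling). Note that ratios of the mean constants generally differ from
    the mean of per-subject ratios; derived quantities should therefore be
    computed per subject and then averaged, which is what this does when
    given per-subject :class:`DerivedPK` objects.
    """
    if len(per_subject) < 2:
        raise ValueError("population summary needs at least 2 subjects")
    rows = []
    for item in per_subject:
        if isinstance(item, MacroParams):
            d = _macro_as_dict(item)
        elif is_dataclass(item):
            d = asdict(item)
        else:
            d = dict(item)
        rows.append({k: v for k, v in d.items() if isinstance(v, (int, float))})
    df = pd.DataFrame(rows)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


def _macro_as_dict(macro: MacroParams) -> dict[str, float]:
    names = [("A", "alpha"), ("B", "beta"), ("C", "gamma")]
    out: dict[str, float] = {}
    for (cname, ename), coef, exp in zip(names, macro.coefficients, macro.exponents):
        out[cname] = coef
        out[ename] = exp
    return out
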