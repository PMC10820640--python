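"""Total-error bioanalytical method-validation statistics.

A validated quantitative assay is judged not on bias and precision
separately but on *total error*: at each concentration level, a
β-expectation tolerance interval for the relative error of a future single
measurement is computed from p series × n replicates of validation
standards, and the method is accepted over the range where every interval
lies inside the ±acceptance limits (the *accuracy profile*). The interval
construction follows Mee's β-expectation tolerance interval for the
balanced one-way random-effects model (series as the random factor), with
Satterthwaite degrees of freedom — the standard construction behind
published accuracy-profile software.

Also provided: variance-component precision (repeatability and
intermediate precision RSD%), the analytic risk of a result falling
outside the acceptance limits, matrix factors and IS-normalised matrix
effects, dilution integrity, ion-ratio CV (specificity), and stability
acceptance bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import (
    LevelAccuracy,
    MatrixEffectResult,
    PrecisionComponents,
    ToleranceInterval,
    ValidationRun,
)

__all__ = [
    "relative_bias",
    "precision_components",
    "beta_expectation_interval",
    "accuracy_profile",
    "risk_outside_acceptance",
    "matrix_factor",
    "is_normalized_mf",
    "matrix_effect_summary",
    "dilution_integrity",
    "ion_ratio_cv",
    "stability_check",
    "AccuracyProfile",
    "DilutionIntegrityResult",
    "StabilityResult",
    "plot_accuracy_profile",
]


def relative_bias(measured, nominal: float) -> float:
    """100 * (mean(measured) - nominal) / nominal, in %."""
    m = np.asarray(measured, dtype=float)
    if m.size == 0:
        raise ValueError("need at least one replicate")
    if nominal <= 0:
        raise ValueError("nominal must be positive")
    return float(100.0 * (m.mean() - nominal) / nominal)


@dataclass(frozen=True)
class _Anova:
    """One-way random-effects decomposition of one validation level."""

    grand_mean: float
    msw: float  # within-series mean square
    msb: float  # between-series mean square
    n_series: int
    n0: float  # replicates per series (harmonic-style for unbalanced)
    n_total: int
    sigma2_within: float
    sigma2_between: float  # truncated at 0

    @property
    def sigma2_ip(self) -> float:
        return self.sigma2_within + self.sigma2_between


def _anova_one_way(run: ValidationRun, level: float) -> _Anova:
    sub = run.at_level(level)
    groups = [g["measured"].to_numpy() for _, g in sub.groupby("series")]
    p = len(groups)
    if p < 2:
        raise ValueError("need at least 2 series for variance components")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 replicates per series")
    sizes = np.array([len(g) for g in groups], dtype=float)
    N = sizes.sum()
    grand = float(np.concatenate(groups).mean())
    means = np.array([g.mean() for g in groups])
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msw = ssw / (N - p)
    ssb = float((sizes * (means - grand) ** 2).sum())
    msb = ssb / (p - 1)
    # n0 reduces to n for balanced designs; method-of-moments otherwise
    n0 = float((N - (sizes**2).sum() / N) / (p - 1))
    sigma2_b = max(0.0, (msb - msw) / n0)
    return _Anova(
        grand_mean=grand,
        msw=msw,
        msb=msb,
        n_series=p,
        n0=n0,
        n_total=int(N),
        sigma2_within=msw,
        sigma2_between=sigma2_b,
    )


def precision_components(run: ValidationRun, level: float) -> PrecisionComponents:
    """Repeatability and intermediate-precision RSD% at one level.

    One-way random-effects ANOVA with series as the random factor:
    repeatability uses the within-series variance only; intermediate
    precision adds the (zero-truncated) between-series component.
    """
    a = _anova_one_way(run, level)
    return PrecisionComponents(
        repeatability_rsd=100.0 * math.sqrt(a.sigma2_within) / a.grand_mean,
        intermediate_precision_rsd=100.0 * math.sqrt(a.sigma2_ip) / a.grand_mean,
    )


def beta_expectation_interval(
    run: ValidationRun, level: float, beta: float = 0.95
) -> ToleranceInterval:
    """β-expectation tolerance interval on relative error (%) at one level.

    Balanced one-way random model (Mee): with R = sigma2_B/sigma2_W,
    B^2 = (R+1)/(nR+1) and Satterthwaite degrees of freedom, the interval is

        bias ± t_{(1+β)/2, ν} * sqrt(1 + 1/(p n B^2)) * s_IP.

    A single-series run falls back to the ordinary Student prediction
    interval mean ± t_{(1+β)/2, n-1} * s * sqrt(1 + 1/n) and is flagged.
    """
    if not 0 < beta < 1:
        raise ValueError("beta must be in (0, 1)")
    sub = run.at_level(level)
    n_series = sub["series"].nunique()
    if n_series == 1:
        y = sub["measured"].to_numpy()
        n = len(y)
        if n < 2:
            raise ValueError("need at least 2 replicates")
        mean, sd = float(y.mean()), float(y.std(ddof=1))
        half = stats.t.ppf((1 + beta) / 2, n - 1) * sd * math.sqrt(1 + 1 / n)
        bias = 100.0 * (mean - level) / level
        half_pct = 100.0 * half / level
        return ToleranceInterval(
            lower_pct=bias - half_pct,
            upper_pct=bias + half_pct,
            beta=beta,
            dof=n - 1,
            k=float(half / sd) if sd > 0 else 0.0,
            method="student_prediction",
            single_series=True,
        )
    a = _anova_one_way(run, level)
    bias = 100.0 * (a.grand_mean - level) / level
    p, n = a.n_series, a.n0
    s_ip = math.sqrt(a.sigma2_ip)
    if s_ip == 0.0:
        return ToleranceInterval(bias, bias, beta, float(p * n - 1), 0.0,
                                 "mee_one_way_random")
    # cap R so the sigma2_W -> 0 limit stays finite (df -> p-1, B^2 -> 1/n)
    R = min(a.sigma2_between / a.sigma2_within, 1e12) if a.sigma2_within > 0 else 1e12
    b2 = (R + 1.0) / (n * R + 1.0)
    dof = (R + 1.0) ** 2 / ((R + 1.0 / n) ** 2 / (p - 1) + (1.0 - 1.0 / n) / (p * n))
    k = stats.t.ppf((1 + beta) / 2, dof) * math.sqrt(1.0 + 1.0 / (p * n * b2))
    half_pct = 100.0 * k * s_ip / level
    return ToleranceInterval(
        lower_pct=bias - half_pct,
        upper_pct=bias + half_pct,
        beta=beta,
        dof=float(dof),
        k=float(k),
        method="mee_one_way_random",
    )


def risk_outside_acceptance(
    bias: float, ip_sd: float, acceptance: float, df: float = math.inf
) -> float:
    """Probability (%) that a future result falls outside ±acceptance.

    The relative error of a future single measurement is modelled as a
    location-scale Student variable centred at ``bias`` with scale
    ``ip_sd`` (both in %) and ``df`` effective degrees of freedom
    (df = inf gives the normal model).
    """
    if ip_sd < 0:
        raise ValueError("ip_sd must be non-negative")
    if acceptance <= 0:
        raise ValueError("acceptance must be positive")
    if ip_sd == 0:
        return 0.0 if abs(bias) <= acceptance else 100.0
    if math.isinf(df):
        cdf = stats.norm.cdf
        inside = cdf((acceptance - bias) / ip_sd) - cdf((-acceptance - bias) / ip_sd)
    else:
        inside = stats.t.cdf((acceptance - bias) / ip_sd, df) - stats.t.cdf(
            (-acceptance - bias) / ip_sd, df
        )
    return float(100.0 * (1.0 - inside))


@dataclass(frozen=True)
class AccuracyProfile:
    levels: tuple[LevelAccuracy, ...]
    acceptance: float  # ± %
    beta: float
    valid: bool  # every tolerance interval inside ±acceptance


def accuracy_profile(
    run: ValidationRun, acceptance: float = 20.0, beta: float = 0.95
) -> AccuracyProfile:
    """Per-level β-expectation tolerance bounds and the overall verdict.

    The method is "valid" over the tested range iff, at every level, the
    tolerance interval is contained in [-acceptance, +acceptance]
    (boundaries inclusive). The per-level risk of an out-of-acceptance
    result is computed from the same bias/precision/df estimates.
    """
    levels = run.levels
    if len(levels) < 2:
        raise ValueError("an accuracy profile needs at least 2 levels")
    rows = []
    valid = True
    for level in levels:
        sub = run.at_level(level)
        bias = relative_bias(sub["measured"].to_numpy(), level)
        interval = beta_expectation_interval(run, level, beta)
        if interval.single_series:
            y = sub["measured"].to_numpy()
            rep = ip = 100.0 * y.std(ddof=1) / y.mean()
        else:
            rep, ip = precision_components(run, level)
        a = _anova_one_way(run, level) if not interval.single_series else None
        ip_sd_pct = (
            100.0 * math.sqrt(a.sigma2_ip) / level
            if a is not None
            else 100.0 * sub["measured"].std(ddof=1) / level
        )
        risk = risk_outside_acceptance(bias, ip_sd_pct, acceptance, interval.dof)
        rows.append(
            LevelAccuracy(
                level=level,
                relative_bias=bias,
                repeatability_rsd=rep,
                intermediate_precision_rsd=ip,
                tolerance_low=interval.lower_pct,
                tolerance_high=interval.upper_pct,
                risk_outside=risk,
            )
        )
        if interval.lower_pct < -acceptance or interval.upper_pct > acceptance:
            valid = False
    return AccuracyProfile(tuple(rows), acceptance, beta, valid)


def plot_accuracy_profile(profile: AccuracyProfile, ax=None):
    """Accuracy-profile plot: bias dots, tolerance band, ±acceptance lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    levels = [la.level for la in profile.levels]
    bias = [la.relative_bias for la in profile.levels]
    lo = [la.tolerance_low for la in profile.levels]
    hi = [la.tolerance_high for la in profile.levels]
    ax.fill_between(levels, lo, hi, alpha=0.25, label="β-expectation tolerance")
    ax.plot(levels, bias, "o-", label="relative bias")
    ax.axhline(profile.acceptance, color="red", ls="--", label="acceptance limits")
    ax.axhline(-profile.acceptance, color="red", ls="--")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xscale("log")
    ax.set_xlabel("nominal concentration (ng/mL)")
    ax.set_ylabel("relative error (%)")
    ax.legend()
    return ax


# ---------------------------------------------------------------------------
# Matrix effects, dilution integrity, specificity, stability


def matrix_factor(area_spiked_post_extraction: float, area_neat: float) -> float:
    """Peak-area ratio: matrix-present (post-extraction spike) over neat."""
    if area_spiked_post_extraction <= 0 or area_neat <= 0:
        raise ValueError("peak areas must be positive")
    return area_spiked_post_extraction / area_neat


def is_normalized_mf(mf_analyte: float, mf_is: float) -> MatrixEffectResult:
    """IS-normalised matrix factor: MF(analyte) / MF(internal standard)."""
    return MatrixEffectResult(mf_analyte=mf_analyte, mf_is=mf_is)


def matrix_effect_summary(results: list[MatrixEffectResult]) -> tuple[float, float]:
    """(mean, CV%) of the IS-normalised matrix factors across matrix lots."""
    if len(results) < 2:
        raise ValueError("need at least 2 matrix lots")
    vals = np.array([r.is_normalized_mf for r in results])
    return float(vals.mean()), float(100.0 * vals.std(ddof=1) / vals.mean())


@dataclass(frozen=True)
class DilutionIntegrityResult:
    deviations_pct: tuple[float, ...]
    mean_pct: float
    sd_pct: float
    passed: bool


def dilution_integrity(
    measured,
    target: float,
    limit: float = 15.0,
    *,
    criterion: str = "all",
) -> DilutionIntegrityResult:
    """Per-replicate deviation from the dilution target and pass/fail.

    ``criterion='all'`` (default) requires every |deviation| <= limit;
    ``criterion='mean'`` applies the limit to the mean deviation only.
    Boundaries are inclusive.
    """
    m = np.asarray(measured, dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 replicates")
    if target <= 0:
        raise ValueError("target must be positive")
    dev = 100.0 * (m - target) / target
    if criterion == "all":
        passed = bool(np.all(np.abs(dev) <= limit))
    elif criterion == "mean":
        passed = bool(abs(dev.mean()) <= limit)
    else:
        raise ValueError("criterion must be 'all' or 'mean'")
    return DilutionIntegrityResult(
        deviations_pct=tuple(float(d) for d in dev),
        mean_pct=float(dev.mean()),
        sd_pct=float(dev.std(ddof=1)),
        passed=passed,
    )


def ion_ratio_cv(quant_areas, qual_areas) -> float:
    """CV% of the qualifier/quantifier peak-area ratio across samples."""
    q = np.asarray(quant_areas, dtype=float)
    i = np.asarray(qual_areas, dtype=float)
    if q.shape != i.shape:
        raise ValueError("paired area arrays must have equal length")
    if q.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(q <= 0) or np.any(i <= 0):
        raise ValueError("peak areas must be positive")
    ratios = i / q
    return float(100.0 * ratios.std(ddof=1) / ratios.mean())


@dataclass(frozen=True)
class StabilityResult:
    deviation_pct: float
    passed: bool


def stability_check(measured: float, target: float, limit: float = 15.0) -> StabilityResult:
    """Deviation from the target (%) and inclusive ±limit acceptance."""
    if target <= 0:
        raise ValueError("target must be positive")
    dev = 100.0 * (measured - target) / target
    return StabilityResult(deviation_pct=float(dev), passed=bool(abs(dev) <= limit))
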