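"""Nested-model comparison between compartmental fits.

Adding a compartment always lowers the weighted residual sum of squares;
whether the improvement is worth two extra parameters is judged with the
extra-sum-of-squares F-test

    F = [(WRSS_r - WRSS_f)/(df_r - df_f)] / (WRSS_f/df_f),

compared to the F(df_r - df_f, df_f) distribution. AIC and weighted R^2
deltas are reported alongside. The AIC convention here is
n ln(WRSS/n) + 2p; AIC values are only comparable within this package,
not across software using other conventions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import FitDiagnostics

__all__ = [
    "aic",
    "r_squared_weighted",
    "f_test_nested",
    "compare_models",
    "FTestResult",
    "ModelSelectionReport",
]


def aic(wrss: float, n_points: int, n_params: int) -> float:
    """AIC = n ln(WRSS/n) + 2p. A perfect fit (WRSS = 0) returns -inf."""
    if n_points <= n_params:
        raise ValueError("n_points must exceed n_params")
    if wrss < 0:
        raise ValueError("WRSS cannot be negative")
    if wrss == 0:
        warnings.warn("WRSS is zero; AIC is -inf", RuntimeWarning, stacklevel=2)
        return float("-inf")
    return n_points * math.log(wrss / n_points) + 2 * n_params


def r_squared_weighted(obs, pred, weights) -> float:
    """Weighted coefficient of determination, 1 - WRSS/WTSS.

    WTSS is taken about the weighted mean of the observations.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    w = np.asarray(weights, dtype=float)
    if obs.shape != pred.shape or obs.shape != w.shape:
        raise ValueError("obs, pred and weights must be aligned")
    wrss = float(np.sum(w * (obs - pred) ** 2))
    wmean = float(np.sum(w * obs) / np.sum(w))
    wtss = float(np.sum(w * (obs - wmean) ** 2))
    if wtss == 0:
        raise ValueError("observations are constant in the weighted metric")
    return 1.0 - wrss / wtss


@dataclass(frozen=True)
class FTestResult:
    f_statistic: float
    df_num: int
    df_den: int
    critical_value: float
    p_value: float
    alpha: float
    prefer_full: bool


def f_test_nested(
    wrss_reduced: float,
    df_reduced: int,
    wrss_full: float,
    df_full: int,
    alpha: float = 0.05,
) -> FTestResult:
    """Extra-sum-of-squares F-test between nested fits.

    ``prefer_full`` is True iff F exceeds the upper-alpha critical value of
    F(df_reduced - df_full, df_full).
    """
    if not df_reduced > df_full >= 1:
        raise ValueError("need df_reduced > df_full >= 1")
    if wrss_full <= 0:
        raise ValueError("wrss_full must be positive")
    if wrss_full > wrss_reduced:
        warnings.warn(
            "full model has larger WRSS than reduced model; fits may not be nested "
            "or the full fit did not converge",
            RuntimeWarning,
            stacklevel=2,
        )
    df_num = df_reduced - df_full
    f_stat = ((wrss_reduced - wrss_full) / df_num) / (wrss_full / df_full)
    critical = float(stats.f.ppf(1.0 - alpha, df_num, df_full))
    p_value = float(stats.f.sf(f_stat, df_num, df_full))
    return FTestResult(
        f_statistic=float(f_stat),
        df_num=df_num,
        df_den=df_full,
        critical_value=critical,
        p_value=p_value,
        alpha=alpha,
        prefer_full=bool(f_stat > critical),
    )


@dataclass(frozen=True)
class ModelSelectionReport:
    pooled: FTestResult
    per_subject: dict[str, FTestResult]
    selected: str  # "reduced" or "full"
    mean_delta_aic: float  # AIC(full) - AIC(reduced)
    mean_delta_r_squared: float  # R2(full) - R2(reduced)
    n_subjects_preferring_full: int = field(default=0)


def compare_models(
    fits_reduced: dict[str, FitDiagnostics],
    fits_full: dict[str, FitDiagnostics],
    alpha: float = 0.05,
) -> ModelSelectionReport:
    """Compare per-subject nested fits and a pooled mean-WRSS test.

    The pooled path feeds the across-subject mean WRSS of each model (at
    the common residual df) to the F-test; per-subject tests are reported
    alongside and are the recommended basis for new analyses. The overall
    ``selected`` verdict follows the pooled test.
    """
    if set(fits_reduced) != set(fits_full):
        raise ValueError("reduced and full fits must cover the same subjects")
    if not fits_reduced:
        raise ValueError("no fits supplied")
    per_subject = {
        sid: f_test_nested(
            fits_reduced[sid].wrss,
            fits_reduced[sid].df,
            fits_full[sid].wrss,
            fits_full[sid].df,
            alpha,
        )
        for sid in sorted(fits_reduced)
    }
    mean_wrss_r = float(np.mean([f.wrss for f in fits_reduced.values()]))
    mean_wrss_f = float(np.mean([f.wrss for f in fits_full.values()]))
    df_r = int(round(np.mean([f.df for f in fits_reduced.values()])))
    df_f = int(round(np.mean([f.df for f in fits_full.values()])))
    pooled = f_test_nested(mean_wrss_r, df_r, mean_wrss_f, df_f, alpha)
    mean_delta_aic = float(
        np.mean(
            [fits_full[s].aic - fits_reduced[s].aic for s in fits_reduced]
        )
    )
    mean_delta_r2 = float(
        np.mean(
            [fits_full[s].r_squared - fits_reduced[s].r_squared for s in fits_reduced]
        )
    )
    return ModelSelectionReport(
        pooled=pooled,
        per_subject=per_subject,
        selected="full" if pooled.prefer_full else "reduced",
        mean_delta_aic=mean_delta_aic,
        mean_delta_r_squared=mean_delta_r2,
        n_subjects_preferring_full=sum(r.prefer_full for r in per_subject.values()),
    )
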