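"""Non-compartmental analysis: Cmax, Tmax, AUC_last, dose normalisation.

BLQ convention: below-quantification points interior to the profile are
excluded; trailing BLQ points truncate AUC_last at the last quantifiable
sample. No back-extrapolation to t = 0 is performed by default, matching
the AUC_last (not AUC_0-t) definition; ``c0_extrapolated`` offers the
optional C(0) = sum-of-coefficients bolus extension.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .datatypes import MacroParams, NcaResult, SubjectProfile

__all__ = [
    "auc_linear_trapezoid",
    "cmax_tmax",
    "nca_profile",
    "dose_normalize",
]


def auc_linear_trapezoid(times, concentrations) -> float:
    """Linear-trapezoid AUC over the supplied points (ng*h/mL)."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(c, t))


def cmax_tmax(profile: SubjectProfile) -> tuple[float, float]:
    """Maximum quantifiable concentration and its time; ties -> earliest."""
    t, c = profile.quantifiable()
    if t.size == 0:
        raise ValueError("profile has no quantifiable points")
    idx = int(np.argmax(c))  # argmax returns the first maximum: earliest time
    return float(c[idx]), float(t[idx])


def nca_profile(
    profile: SubjectProfile,
    *,
    c0_extrapolated: MacroParams | None = None,
) -> NcaResult:
    """Cmax, Tmax and AUC_last for one subject.

    If ``c0_extrapolated`` is given, its back-extrapolated C(0) is prepended
    at t = 0 before integration (off by default).
    """
    t, c = profile.quantifiable()
    cmax, tmax = cmax_tmax(profile)
    if c0_extrapolated is not None:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[c0_extrapolated.c0], c])
    auc = auc_linear_trapezoid(t, c) if t.size >= 2 else 0.0
    return NcaResult(
        subject_id=profile.subject_id,
        cmax=cmax,
        tmax=tmax,
        auc_last=auc,
        dose=profile.dose,
    )


def dose_normalize(result: NcaResult, dose: float | None = None) -> NcaResult:
    """Divide Cmax and AUC_last by the administered dose (ng)."""
    dose = result.dose if dose is None else dose
    if dose <= 0:
        raise ValueError("dose must be positive")
    return replace(
        result,
        cmax_per_dose=result.cmax / dose,
        auc_last_per_dose=result.auc_last / dose,
    )
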