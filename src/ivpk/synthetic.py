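"""Synthetic study data with the statistical structure the analysis assumes.

The generator emulates an exploratory IV-bolus pharmacokinetic study in
piglets: three animals of 8–10 kg receive 0.3 mg/kg of a 1.2 mg/mL
solution, plasma is sampled at 5, 10, 20, 30, 45, 60, 90 min and 2, 4 and
8 h, and concentrations decay bi-exponentially with proportional
measurement error (the error structure that motivates 1/y² fitting
weights). Bioanalytical validation runs are emulated as 3 series × 5
replicates at 4 nominal levels with a shared per-series bias and a
within-series residual. Default magnitudes are stated in docs/methods.md;
they are synthetic choices, not estimates of any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartmental import macro_to_micro, micro_to_macro, predict_concentration
from .datatypes import MacroParams, MicroParams, SubjectProfile, ValidationRun

__all__ = [
    "DosingRecord",
    "SamplingSchedule",
    "ErrorModel",
    "compute_injection_volume",
    "make_dosing_record",
    "simulate_subject_profile",
    "simulate_cohort",
    "simulate_validation_run",
    "DEFAULT_SCHEDULE_H",
    "EARLY_EXIT_SCHEDULE_H",
    "STUDY_BODY_WEIGHTS_KG",
    "STUDY_DOSE_MG_PER_KG",
    "STUDY_SOLUTION_MG_PER_ML",
    "TYPICAL_MACRO_2C",
    "typical_micro_2c",
    "DEFAULT_LLOQ_NG_PER_ML",
]

# Sampling schedule of the emulated protocol (h): 5, 10, 20, 30, 45, 60,
# 90 min, then 2, 4 and 8 h. No t=0 sample exists for an IV bolus.
DEFAULT_SCHEDULE_H: tuple[float, ...] = (
    1 / 12, 1 / 6, 1 / 3, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 8.0,
)
# Variant for a subject withdrawn before 8 h with a substitute 6.5 h sample.
EARLY_EXIT_SCHEDULE_H: tuple[float, ...] = (
    1 / 12, 1 / 6, 1 / 3, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 6.5,
)

STUDY_BODY_WEIGHTS_KG: dict[str, float] = {"P1": 9.45, "P2": 9.04, "P3": 8.85}
STUDY_DOSE_MG_PER_KG: float = 0.3
STUDY_SOLUTION_MG_PER_ML: float = 1.2
DEFAULT_LLOQ_NG_PER_ML: float = 0.5

# Central two-compartment disposition used as simulation truth
# (coefficients ng/mL, exponents 1/h).
TYPICAL_MACRO_2C = MacroParams(coefficients=(542.53, 168.95), exponents=(3.71, 0.34))


def typical_micro_2c(dose_ng: float | None = None) -> MicroParams:
    """Rate-constant form of the default disposition truth.

    ``dose_ng`` fixes V1 via V1 = dose/C(0); the default is the mean study
    dose (mean body weight × 0.3 mg/kg).
    """
    if dose_ng is None:
        mean_weight = float(np.mean(list(STUDY_BODY_WEIGHTS_KG.values())))
        dose_ng = mean_weight * STUDY_DOSE_MG_PER_KG * 1e6
    return macro_to_micro(TYPICAL_MACRO_2C, dose_ng)


@dataclass(frozen=True)
class DosingRecord:
    subject_id: str
    body_weight: float  # kg
    dose_per_kg: float  # mg/kg
    solution_concentration: float  # mg/mL
    injected_volume: float  # mL

    def __post_init__(self) -> None:
        for name in ("body_weight", "dose_per_kg", "solution_concentration",
                     "injected_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def dose_ng(self) -> float:
        return self.body_weight * self.dose_per_kg * 1e6


@dataclass(frozen=True)
class SamplingSchedule:
    times: tuple[float, ...]  # h, post-dose

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and positive")
        object.__setattr__(self, "times", tuple(float(x) for x in t))


@dataclass(frozen=True)
class ErrorModel:
    """Measurement-noise model: C_obs = C_true (1 + eps_prop) + eps_add."""

    proportional_cv: float = 0.10  # fraction, not %
    additive_sd: float = 0.0  # ng/mL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


def compute_injection_volume(
    body_weight: float, dose_per_kg: float, solution_concentration: float
) -> float:
    """Injected volume (mL) = weight (kg) × dose (mg/kg) / solution (mg/mL)."""
    if body_weight <= 0 or dose_per_kg <= 0 or solution_concentration <= 0:
        raise ValueError("all dosing inputs must be positive")
    return body_weight * dose_per_kg / solution_concentration


def make_dosing_record(
    subject_id: str,
    body_weight: float,
    dose_per_kg: float = STUDY_DOSE_MG_PER_KG,
    solution_concentration: float = STUDY_SOLUTION_MG_PER_ML,
) -> DosingRecord:
    return DosingRecord(
        subject_id=subject_id,
        body_weight=body_weight,
        dose_per_kg=dose_per_kg,
        solution_concentration=solution_concentration,
        injected_volume=compute_injection_volume(
            body_weight, dose_per_kg, solution_concentration
        ),
    )


def simulate_subject_profile(
    micro: MicroParams,
    dose: float,
    schedule: SamplingSchedule | None = None,
    error: ErrorModel | None = None,
    *,
    subject_id: str = "SIM",
    lloq: float = DEFAULT_LLOQ_NG_PER_ML,
    floor: float = 0.0,
) -> SubjectProfile:
    """Simulate one subject's concentration-time profile.

    Noiseless concentrations are the analytic sum-of-exponentials solution;
    noise follows ``error`` with its own seed (reproducible). Values driven
    negative by noise are clamped to ``floor`` and flagged BLQ, as are
    values below ``lloq``; flagged points are retained in the profile but
    excluded from fits and NCA by :meth:`SubjectProfile.quantifiable`.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    schedule = schedule or SamplingSchedule(DEFAULT_SCHEDULE_H)
    times = np.asarray(schedule.times)
    macro = micro_to_macro(micro, dose)
    true = np.atleast_1d(predict_concentration(macro, times)).astype(float)
    obs = true.copy()
    if error is not None and (error.proportional_cv > 0 or error.additive_sd > 0):
        rng = np.random.default_rng(error.seed)
        obs = true * (1.0 + rng.normal(0.0, error.proportional_cv, true.size))
        obs += rng.normal(0.0, error.additive_sd, true.size)
    blq = obs < lloq
    negative = obs < floor
    obs = np.where(negative, floor, obs)
    blq |= negative
    return SubjectProfile(
        subject_id=subject_id, dose=dose, times=times, concentrations=obs, blq=blq
    )


def simulate_cohort(
    micro: MicroParams | None = None,
    weights_kg: dict[str, float] | None = None,
    *,
    proportional_cv: float = 0.10,
    seed: int = 0,
    schedules: dict[str, SamplingSchedule] | None = None,
) -> list[SubjectProfile]:
    """Simulate the default three-piglet IV-bolus study.

    Every subject shares the disposition ``micro`` (default: the typical
    two-compartment truth); doses scale with body weight at 0.3 mg/kg.
    Per-subject noise seeds are derived from ``seed``.
    """
    weights_kg = weights_kg or STUDY_BODY_WEIGHTS_KG
    if micro is None:
        micro = typical_micro_2c()
    profiles = []
    for i, (sid, weight) in enumerate(sorted(weights_kg.items())):
        dose_ng = weight * STUDY_DOSE_MG_PER_KG * 1e6
        schedule = (schedules or {}).get(sid)
        profiles.append(
            simulate_subject_profile(
                micro,
                dose_ng,
                schedule,
                ErrorModel(proportional_cv=proportional_cv, seed=seed * 1009 + i),
                subject_id=sid,
            )
        )
    return profiles


def simulate_validation_run(
    levels,
    n_series: int = 3,
    n_replicates: int = 5,
    *,
    series_bias_sd: float = 3.0,  # %
    within_cv: float = 4.0,  # %
    overall_bias: float = -2.0,  # %
    seed: int = 0,
) -> ValidationRun:
    """Simulate a p-series × n-replicate validation run at the given levels.

    measured = nominal × (1 + overall_bias + series_effect + residual),
    with the series effect ~ N(0, series_bias_sd) shared by every
    measurement of a series and the residual ~ N(0, within_cv) independent
    per replicate (all three in fractional form internally; arguments
    are percentages).
    """
    levels = [float(x) for x in np.atleast_1d(levels)]
    if any(x <= 0 for x in levels):
        raise ValueError("levels must be positive")
    if n_series < 2 or n_replicates < 2:
        raise ValueError("need at least 2 series and 2 replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_series + 1):
        series_effect = rng.normal(0.0, series_bias_sd / 100.0)
        for level in levels:
            resid = rng.normal(0.0, within_cv / 100.0, n_replicates)
            measured = level * (1.0 + overall_bias / 100.0 + series_effect + resid)
            for m in measured:
                rows.append((s, level, float(m)))
    return ValidationRun(pd.DataFrame(rows, columns=["series", "level", "measured"]))
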