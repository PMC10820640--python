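"""Core value objects shared across the package.

Units are fixed internally: time in hours, concentration in ng/mL, dose in
ng, volume in mL. Conversions belong at the I/O boundary, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MacroParams",
    "MicroParams",
    "DerivedPK",
    "FitDiagnostics",
    "SubjectProfile",
    "NcaResult",
    "CalibrationCurve",
    "ValidationRun",
    "PrecisionComponents",
    "ToleranceInterval",
    "LevelAccuracy",
    "MatrixEffectResult",
]


@dataclass(frozen=True)
class MacroParams:
    """Sum-of-exponentials IV-bolus disposition: C(t) = sum_i coef_i * exp(-exp_i * t).

    Coefficients are in ng/mL, exponents in 1/h. Terms are stored sorted by
    exponent, fastest first, so ``exponents[0]`` is always the (initial)
    distribution rate and ``exponents[-1]`` the terminal elimination rate.
    """

    coefficients: tuple[float, ...]
    exponents: tuple[float, ...]

    def __post_init__(self) -> None:
        coefs = tuple(float(c) for c in self.coefficients)
        exps = tuple(float(e) for e in self.exponents)
        if len(coefs) != len(exps):
            raise ValueError("coefficients and exponents must have equal length")
        if not 1 <= len(coefs) <= 3:
            raise ValueError("supported models have 1 to 3 exponential terms")
        if any(c <= 0 for c in coefs) or any(e <= 0 for e in exps):
            raise ValueError("coefficients and exponents must be positive")
        order = np.argsort(exps)[::-1]
        object.__setattr__(self, "coefficients", tuple(coefs[i] for i in order))
        object.__setattr__(self, "exponents", tuple(exps[i] for i in order))
        sorted_exps = self.exponents
        for fast, slow in zip(sorted_exps, sorted_exps[1:]):
            if fast <= slow:
                raise ValueError("exponents must be distinct")

    @property
    def n_compartments(self) -> int:
        return len(self.coefficients)

    @property
    def c0(self) -> float:
        """Back-extrapolated concentration at t = 0 (= dose / V1)."""
        return float(sum(self.coefficients))


@dataclass(frozen=True)
class MicroParams:
    """Mammillary-model rate constants (1/h) and central volume V1 (mL).

    ``k10`` is elimination from the central compartment; ``k12``/``k21``
    (and ``k13``/``k31`` for three compartments) are the transfer constants
    to/from the peripheral compartment(s). The degenerate one-compartment
    case is represented by ``k12 = k21 = 0``.
    """

    k10: float
    k12: float
    k21: float
    V1: float
    k13: float | None = None
    k31: float | None = None

    def __post_init__(self) -> None:
        if self.k10 <= 0 or self.V1 <= 0:
            raise ValueError("k10 and V1 must be positive")
        if self.k12 < 0 or self.k21 < 0:
            raise ValueError("transfer constants must be non-negative")
        if (self.k12 > 0) != (self.k21 > 0):
            raise ValueError("k12 and k21 must be both zero or both positive")
        if (self.k13 is None) != (self.k31 is None):
            raise ValueError("k13 and k31 must be given together")
        if self.k13 is not None:
            if self.k13 <= 0 or self.k31 <= 0:
                raise ValueError("k13 and k31 must be positive for three compartments")
            if self.k12 == 0:
                raise ValueError("three-compartment model requires k12, k21 > 0")

    @property
    def n_compartments(self) -> int:
        if self.k13 is not None:
            return 3
        return 2 if self.k12 > 0 else 1


@dataclass(frozen=True)
class DerivedPK:
    """Secondary disposition descriptors.

    vss -- volume of distribution at steady state (mL)
    cl -- clearance, V1 * k10 (mL/h)
    t_half_dist / t_half_elim -- distribution and terminal half-lives (h)
    depth -- k10/k12, elimination vs. tissue-uptake speed
    capacity -- k12/k21, tissue uptake vs. return
    fc -- terminal exponent / k10, fraction of body drug in the central
          compartment during the terminal phase
    """

    vss: float
    cl: float
    t_half_dist: float
    t_half_elim: float
    depth: float
    capacity: float
    fc: float


@dataclass(frozen=True)
class FitDiagnostics:
    wrss: float
    df: int
    aic: float
    r_squared: float
    n_params: int
    n_points: int

    def __post_init__(self) -> None:
        if self.df != self.n_points - self.n_params:
            raise ValueError("df must equal n_points - n_params")
        if self.df < 1:
            raise ValueError("model leaves no residual degrees of freedom")
        if self.wrss < 0:
            raise ValueError("WRSS cannot be negative")


@dataclass(frozen=True)
class SubjectProfile:
    """One animal's dose and concentration-time series."""

    subject_id: str
    dose: float  # ng
    times: np.ndarray  # h, strictly increasing
    concentrations: np.ndarray  # ng/mL
    blq: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        concs = np.asarray(self.concentrations, dtype=float)
        blq = (
            np.zeros(times.shape, dtype=bool)
            if self.blq is None
            else np.asarray(self.blq, dtype=bool)
        )
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if times.ndim != 1 or times.shape != concs.shape or times.shape != blq.shape:
            raise ValueError("times, concentrations and blq must be 1-D and aligned")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(concs[~blq] < 0):
            raise ValueError("quantifiable concentrations must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", concs)
        object.__setattr__(self, "blq", blq)

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations of points above the quantification limit."""
        mask = ~self.blq & (self.concentrations > 0)
        return self.times[mask], self.concentrations[mask]


@dataclass(frozen=True)
class NcaResult:
    subject_id: str
    cmax: float  # ng/mL
    tmax: float  # h
    auc_last: float  # ng*h/mL
    dose: float  # ng
    cmax_per_dose: float | None = None
    auc_last_per_dose: float | None = None


@dataclass(frozen=True)
class CalibrationCurve:
    """Weighted linear calibration: response = intercept + slope * concentration."""

    slope: float
    intercept: float
    weight_exponent: float
    r_squared: float
    lloq: float  # ng/mL
    uloq: float  # ng/mL

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be non-zero")
        if not self.lloq < self.uloq:
            raise ValueError("lloq must be below uloq")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


class ValidationRun:
    """Nominal-vs-measured replicates organised by series and level.

    Thin wrapper around a DataFrame with columns ``series``, ``level``
    (nominal ng/mL) and ``measured`` (ng/mL).
    """

    def __init__(self, data: pd.DataFrame):
        required = {"series", "level", "measured"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = data.loc[:, ["series", "level", "measured"]].copy()
        df["level"] = df["level"].astype(float)
        df["measured"] = df["measured"].astype(float)
        if (df["level"] <= 0).any():
            raise ValueError("nominal levels must be positive")
        if (df["measured"] <= 0).any():
            raise ValueError("measured concentrations must be positive")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[object, float, float]]
    ) -> "ValidationRun":
        """Build from (series, level, measured) triples."""
        return cls(pd.DataFrame(records, columns=["series", "level", "measured"]))

    @property
    def levels(self) -> list[float]:
        return sorted(self.data["level"].unique())

    @property
    def series(self) -> list:
        return sorted(self.data["series"].unique())

    def at_level(self, level: float) -> pd.DataFrame:
        sub = self.data[np.isclose(self.data["level"], level)]
        if sub.empty:
            raise KeyError(f"no replicates at nominal level {level}")
        return sub

    def __len__(self) -> int:
        return len(self.data)


class PrecisionComponents(NamedTuple):
    repeatability_rsd: float  # %
    intermediate_precision_rsd: float  # %


@dataclass(frozen=True)
class ToleranceInterval:
    """β-expectation tolerance interval on relative error (%)."""

    lower_pct: float
    upper_pct: float
    beta: float
    dof: float
    k: float
    method: str  # "mee_one_way_random" or "student_prediction"
    single_series: bool = False


@dataclass(frozen=True)
class LevelAccuracy:
    level: float  # ng/mL
    relative_bias: float  # %
    repeatability_rsd: float  # %
    intermediate_precision_rsd: float  # %
    tolerance_low: float  # %
    tolerance_high: float  # %
    risk_outside: float  # %


@dataclass(frozen=True)
class MatrixEffectResult:
    mf_analyte: float
    mf_is: float
    is_normalized_mf: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mf_analyte <= 0 or self.mf_is <= 0:
            raise ValueError("matrix factors must be positive")
        object.__setattr__(self, "is_normalized_mf", self.mf_analyte / self.mf_is)
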