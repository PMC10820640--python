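"""Weighted linear calibration curves and back-calculation.

LC-MS/MS bioanalysis regresses the analyte/internal-standard peak-area
ratio on the nominal concentration with weights 1/x^k (k = 0, 1 or 2).
Assay noise is typically proportional to concentration, so 1/x^2 weighting
equalises the relative errors across the range and keeps the lowest
standards from being dominated by the highest ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datatypes import CalibrationCurve

__all__ = [
    "fit_weighted_calibration",
    "predict_response",
    "back_calculate",
    "dilution_correct",
    "BackCalculated",
]


def fit_weighted_calibration(
    nominal,
    response,
    weight_exponent: float = 2.0,
    *,
    lloq: float | None = None,
    uloq: float | None = None,
) -> CalibrationCurve:
    """Fit response = a + b * nominal by WLS with weights 1/nominal^exponent.

    Replicate standards at a level enter as individual points. The reported
    r^2 is the weighted coefficient of determination. ``lloq``/``uloq``
    default to the lowest/highest nominal level of the fit.
    """
    x = np.asarray(nominal, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("nominal and response must be aligned 1-D arrays")
    if np.any(x <= 0):
        raise ValueError("nominal concentrations must be positive")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    weights = 1.0 / x**weight_exponent
    model = sm.WLS(y, sm.add_constant(x), weights=weights)
    res = model.fit()
    slope = float(res.params[1])
    if slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    return CalibrationCurve(
        slope=slope,
        intercept=float(res.params[0]),
        weight_exponent=float(weight_exponent),
        r_squared=min(1.0, float(res.rsquared)),
        lloq=float(x.min()) if lloq is None else float(lloq),
        uloq=float(x.max()) if uloq is None else float(uloq),
    )


def predict_response(curve: CalibrationCurve, concentration) -> np.ndarray | float:
    """Fitted response at the given concentration(s)."""
    c = np.asarray(concentration, dtype=float)
    out = curve.intercept + curve.slope * c
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BackCalculated:
    concentration: float  # ng/mL
    within_range: bool  # inside [lloq, uloq] (inclusive)


def back_calculate(curve: CalibrationCurve, response: float) -> BackCalculated:
    """Invert the calibration line: (response - intercept)/slope.

    Results outside [lloq, uloq] are flagged (boundaries count as in-range).
    """
    conc = (response - curve.intercept) / curve.slope
    tol = 1e-9 * max(1.0, curve.uloq)
    within = (curve.lloq - tol) <= conc <= (curve.uloq + tol)
    return BackCalculated(concentration=float(conc), within_range=bool(within))


def dilution_correct(measured: float, dilution_factor: float) -> float:
    """Multiply a diluted-sample result back to the original concentration.

    A d-fold dilution extends the reportable maximum to uloq * d, provided
    dilution integrity has been demonstrated at that factor.
    """
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return measured * dilution_factor
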