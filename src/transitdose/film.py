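"""Radiochromic-film sensitometric calibration.

Calibration film strips receive known doses; their net optical densities
(OD = log10(I0/I)) define a sensitometric curve.  A fourth-order polynomial
is least-squares fitted to dose vs net OD and used to convert film scans to
dose.  The fit is rejected if it is not monotone increasing over the
calibration domain — a non-monotone conversion would be ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ExtrapolationWarning, InvalidCalibrationError, InvalidInputError

__all__ = ["SensitometricCurve", "fit_sensitometric", "od_to_dose"]

POLY_DEGREE = 4


@dataclass(frozen=True)
class SensitometricCurve:
    """Degree-4 polynomial dose(OD) with its calibration OD domain."""

    coefficients: np.ndarray  # ascending powers
    od_min: float
    od_max: float

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, float)
        if coef.size != POLY_DEGREE + 1:
            raise InvalidInputError(f"expected {POLY_DEGREE + 1} coefficients")
        object.__setattr__(self, "coefficients", coef)

    def __call__(self, od):
        return np.polynomial.polynomial.polyval(od, self.coefficients)


def fit_sensitometric(calibration) -> SensitometricCurve:
    """Fit the sensitometric curve from (net OD, dose cGy) pairs.

    Requires at least six points; OD must increase strictly with dose.  The
    fitted polynomial must be monotone increasing over the OD domain, else
    the fit is rejected.
    """
    pairs = sorted((float(od), float(dose)) for od, dose in calibration)
    if len(pairs) < POLY_DEGREE + 2:
        raise InvalidCalibrationError(
            f"need >= {POLY_DEGREE + 2} calibration points, got {len(pairs)}"
        )
    od = np.array([p[0] for p in pairs])
    dose = np.array([p[1] for p in pairs])
    if np.any(np.diff(od) <= 0):
        raise InvalidCalibrationError("net OD values must be distinct")
    if np.any(np.diff(dose) <= 0):
        raise InvalidCalibrationError("dose must increase strictly with net OD")
    coef = np.polynomial.polynomial.polyfit(od, dose, POLY_DEGREE)
    curve = SensitometricCurve(coef, od.min(), od.max())
    grid = np.linspace(curve.od_min, curve.od_max, 512)
    deriv = np.polynomial.polynomial.polyval(
        grid, np.polynomial.polynomial.polyder(coef)
    )
    if np.any(deriv < -1e-9 * max(1.0, float(np.abs(deriv).max()))):
        raise InvalidCalibrationError(
            "fitted sensitometric curve is not monotone over the calibration domain"
        )
    return curve


def od_to_dose(curve: SensitometricCurve, od):
    """Convert net optical density to dose (cGy).

    Values outside the calibration domain are evaluated anyway but flagged
    with an :class:`ExtrapolationWarning`.
    """
    od_arr = np.asarray(od, float)
    if np.any(od_arr < curve.od_min - 1e-12) or np.any(od_arr > curve.od_max + 1e-12):
        warnings.warn(
            "optical density outside the calibration domain; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out = curve(od_arr)
    return float(out) if np.ndim(od) == 0 else out
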