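"""Profile metrics and the 2D gamma index.

Profile comparisons follow the transit-dosimetry convention: the reference
is the ion-chamber-like curve, differences are reported in percent of the
local reference dose, and only the region inside the 50% penumbra points of
the reference is analyzed (doses beyond it are low and percent differences
there are over-amplified).

The gamma index combines a dose-difference criterion (percent of a
normalization dose, the reference CAX dose by default) with a
distance-to-agreement (DTA, mm):

    γ(r_ref) = min over r_test of sqrt( (ΔD/ΔD_crit)² + (|Δr|/DTA)² )

Points with γ <= 1 pass.  The test plane is searched on a sub-grid lattice
(bilinear interpolation, step <= 0.05·DTA by default, radius 3·DTA); the
lattice is nested under refinement so a finer search can only lower γ, and
the default step keeps the discretization error below 0.05 γ-units even at
penumbra-steep dose gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import InvalidInputError, InvalidReferenceError, OpenFieldEdgeError
from .plane import DosePlane

__all__ = [
    "Profile",
    "GammaResult",
    "cax_percent_diff",
    "field_edges_50",
    "average_difference",
    "gamma_index",
]


@dataclass(frozen=True)
class Profile:
    """1D dose profile: strictly increasing positions (cm) and doses (cGy)."""

    positions: np.ndarray
    doses: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        dose = np.asarray(self.doses, float)
        if pos.ndim != 1 or pos.shape != dose.shape or pos.size < 2:
            raise InvalidInputError("profile needs matching 1D arrays of length >= 2")
        if np.any(np.diff(pos) <= 0):
            raise InvalidInputError("profile positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "doses", dose)

    def at(self, x) -> np.ndarray:
        """Linear interpolation (no extrapolation beyond the end values)."""
        return np.interp(x, self.positions, self.doses)


def cax_percent_diff(test: Profile, reference: Profile) -> float:
    """100·(test(0) − ref(0))/ref(0), both evaluated at the CAX by
    linear interpolation."""
    for p in (test, reference):
        if not (p.positions[0] <= 0.0 <= p.positions[-1]):
            raise InvalidInputError("profile does not bracket the CAX")
    ref0 = float(reference.at(0.0))
    if ref0 <= 0:
        raise InvalidReferenceError("reference CAX dose must be positive")
    return 100.0 * (float(test.at(0.0)) - ref0) / ref0


def field_edges_50(reference: Profile) -> tuple[float, float]:
    """Outermost crossings of 50% of the CAX dose (linear interpolation)."""
    if not (reference.positions[0] <= 0.0 <= reference.positions[-1]):
        raise InvalidInputError("profile does not bracket the CAX")
    cax = float(reference.at(0.0))
    if cax <= 0:
        raise InvalidReferenceError("reference CAX dose must be positive")
    half = cax / 2.0
    pos, dose = reference.positions, reference.doses
    above = dose >= half
    crossings = []
    for i in range(pos.size - 1):
        if above[i] != above[i + 1]:
            t = (half - dose[i]) / (dose[i + 1] - dose[i])
            crossings.append(pos[i] + t * (pos[i + 1] - pos[i]))
    left = [c for c in crossings if c < 0]
    right = [c for c in crossings if c > 0]
    if not left or not right:
        raise OpenFieldEdgeError("profile never falls below 50% of the CAX dose on both sides")
    return min(left), max(right)


def average_difference(test: Profile, reference: Profile) -> tuple[float, float]:
    """Mean and sample SD of per-point percent differences inside the 50%
    penumbra bounds of the reference.

    The test profile is resampled onto the reference positions within
    [left, right]; each point contributes 100·(test − ref)/ref.
    """
    left, right = field_edges_50(reference)
    mask = (reference.positions >= left) & (reference.positions <= right)
    ref = reference.doses[mask]
    if np.any(ref <= 0):
        raise InvalidReferenceError("reference dose must be positive inside the field")
    tst = test.at(reference.positions[mask])
    diffs = 100.0 * (tst - ref) / ref
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    return mean, sd


@dataclass(frozen=True)
class GammaResult:
    """Gamma map plus pass-rate statistics for one plane comparison."""

    gamma_map: np.ndarray
    pass_rate: float
    dose_criterion: float  # percent
    dta: float             # mm
    low_dose_threshold: float  # percent of the normalization dose
    evaluated: np.ndarray  # bool mask of points entering the pass rate
    normalization_dose: float


def gamma_index(test: DosePlane, reference: DosePlane, dose_pct: float = 3.0,
                dta_mm: float = 3.0, norm: str = "cax",
                norm_value: float | None = None,
                low_dose_pct: float = 10.0,
                search_radius_factor: float = 3.0,
                step_factor: float = 0.05) -> GammaResult:
    """2D gamma index of a test plane against a reference plane.

    ``norm`` selects the dose that the percent criterion refers to:
    ``'cax'`` (reference CAX dose — the default), ``'max'`` (reference
    maximum) or ``'global-value'`` with an explicit ``norm_value`` in cGy.
    Points below ``low_dose_pct`` percent of the normalization dose are
    excluded from the pass rate (the gamma map is still filled everywhere).
    """
    if not (dose_pct > 0 and dta_mm > 0):
        raise InvalidInputError("dose_pct and dta_mm must be positive")
    if norm == "cax":
        d0 = reference.cax()
    elif norm == "max":
        d0 = float(reference.values.max())
    elif norm == "global-value":
        if norm_value is None:
            raise InvalidInputError("norm='global-value' requires norm_value")
        d0 = float(norm_value)
    else:
        raise InvalidInputError(f"unknown normalization {norm!r}")
    if d0 <= 0:
        raise InvalidReferenceError("normalization dose must be positive")

    dta = dta_mm / 10.0  # cm
    dcrit = dose_pct / 100.0 * d0
    radius = search_radius_factor * dta
    # integer sub-grid: nested under refinement, step <= step_factor*dta
    k = int(np.ceil(reference.spacing / (step_factor * dta) - 1e-12))
    k = max(k, 1)
    fine = reference.spacing / k
    m = int(np.ceil(radius / fine - 1e-12))

    ny, nx = reference.values.shape
    fy = reference.origin[1] + fine * np.arange(-m, (ny - 1) * k + m + 1)
    fx = reference.origin[0] + fine * np.arange(-m, (nx - 1) * k + m + 1)

    def _snap_to_bounds(coords: np.ndarray, grid: np.ndarray) -> np.ndarray:
        # fine ticks that mathematically coincide with the test-grid edge can
        # land an ulp outside it and read the zero fill; snap them back
        eps = 1e-6 * fine
        out = coords.copy()
        out[(out < grid[0]) & (out > grid[0] - eps)] = grid[0]
        out[(out > grid[-1]) & (out < grid[-1] + eps)] = grid[-1]
        return out

    fy = _snap_to_bounds(fy, test.y)
    fx = _snap_to_bounds(fx, test.x)
    interp = RegularGridInterpolator((test.y, test.x), test.values,
                                     bounds_error=False, fill_value=0.0)
    gy, gx = np.meshgrid(fy, fx, indexing="ij")
    tf = interp(np.stack([gy, gx], axis=-1))

    rv = reference.values
    g2 = np.full(rv.shape, np.inf)
    r2max = radius**2 + 1e-12
    for di in range(-m, m + 1):
        for dj in range(-m, m + 1):
            r2 = (di * fine) ** 2 + (dj * fine) ** 2
            if r2 > r2max:
                continue
            ts = tf[m + di:m + di + (ny - 1) * k + 1:k,
                    m + dj:m + dj + (nx - 1) * k + 1:k]
            cand = ((ts - rv) / dcrit) ** 2 + r2 / dta**2
            np.minimum(g2, cand, out=g2)
    gamma = np.sqrt(g2)
    evaluated = rv >= low_dose_pct / 100.0 * d0
    if evaluated.any():
        pass_rate = 100.0 * float(np.mean(gamma[evaluated] <= 1.0 + 1e-9))
    else:
        pass_rate = float("nan")
    return GammaResult(gamma, pass_rate, dose_pct, dta_mm, low_dose_pct,
                       evaluated, d0)
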