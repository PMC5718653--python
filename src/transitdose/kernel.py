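"""Triple-Gaussian scatter kernel: realization, convolution, fitting, lookup.

The lateral-scatter kernel is a radially symmetric sum of three Gaussians,

    SK(r) = exp(-r²/A²) + B·exp(-r²/C²) + D·exp(-r²/E²),

with widths A, C, E (cm) and relative amplitudes B, D.  Before use the
realized kernel is normalized so its *discrete* integral (cell sum × cell
area) is exactly one; convolution with a unit kernel then conserves the dose
integral.  The three Gaussians are exchangeable, so fitted parameters are
judged by the kernel's action on profiles, not by their raw values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .errors import (
    FitFailureError,
    GridMismatchError,
    InvalidInputError,
    TruncationWarning,
)
from .plane import DosePlane, bilinear_clamped, centered_coords

__all__ = [
    "ScatterKernelParams",
    "kernel_evaluate",
    "delta_kernel",
    "convolve",
    "fit_kernel",
    "fit_kernel_single",
    "kernel_interpolate",
]

#: Fixed starting point for the kernel fit; documented so fits are reproducible.
DEFAULT_X0 = (0.4, 0.05, 1.2, 0.02, 2.5)
WIDTH_BOUNDS = (0.05, 6.0)
AMPLITUDE_BOUNDS = (0.0, 5.0)


@dataclass(frozen=True)
class ScatterKernelParams:
    """Kernel parameters (A, C, E widths in cm > 0; B, D amplitudes >= 0)."""

    A: float
    B: float
    C: float
    D: float
    E: float

    def __post_init__(self) -> None:
        for name in ("A", "C", "E"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"width {name} must be positive")
        for name in ("B", "D"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"amplitude {name} must be >= 0")

    @property
    def max_width(self) -> float:
        return max(self.A, self.C, self.E)

    def analytic_integral(self) -> float:
        """∫∫ SK dA = π(A² + B·C² + D·E²)."""
        return np.pi * (self.A**2 + self.B * self.C**2 + self.D * self.E**2)

    def second_moment(self) -> float:
        """Mean squared radius ⟨r²⟩ of the normalized kernel (cm²)."""
        num = self.A**4 + self.B * self.C**4 + self.D * self.E**4
        den = self.A**2 + self.B * self.C**2 + self.D * self.E**2
        return num / den

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D, self.E])


def kernel_evaluate(params: ScatterKernelParams, spacing: float,
                    half_width: float | None = None) -> DosePlane:
    """Realize the kernel on a square grid and normalize to unit integral.

    ``half_width`` defaults to 3× the largest width, which captures >= 99.9%
    of the analytic mass; a smaller grid triggers a :class:`TruncationWarning`
    rather than an error.
    """
    if not spacing > 0:
        raise InvalidInputError("kernel spacing must be positive")
    if half_width is None:
        half_width = 3.0 * params.max_width
    c = centered_coords(half_width, spacing)
    if c.size < 1:
        raise InvalidInputError("kernel grid is empty; increase half_width")
    r2 = c[None, :] ** 2 + c[:, None] ** 2
    vals = (np.exp(-r2 / params.A**2)
            + params.B * np.exp(-r2 / params.C**2)
            + params.D * np.exp(-r2 / params.E**2))
    # analytic mass inside radius R for each Gaussian: π w² (1 - e^{-R²/w²})
    R = c[-1]
    captured = np.pi * sum(
        amp * w**2 * (1.0 - np.exp(-(R**2) / w**2))
        for amp, w in ((1.0, params.A), (params.B, params.C), (params.D, params.E))
    )
    if captured / params.analytic_integral() < 0.999:
        warnings.warn(
            f"kernel grid half_width={half_width:.3g} cm captures "
            f"{100 * captured / params.analytic_integral():.2f}% of the analytic mass",
            TruncationWarning,
            stacklevel=2,
        )
    vals /= vals.sum() * spacing**2
    return DosePlane(vals, spacing, (c[0], c[0]), source_distance=None)


def delta_kernel(spacing: float) -> DosePlane:
    """Single-cell identity kernel (discrete delta with unit integral)."""
    return DosePlane(np.array([[1.0 / spacing**2]]), spacing, (0.0, 0.0), None)


def convolve(plane: DosePlane, kernel: DosePlane) -> DosePlane:
    """Linear 2D convolution of a dose plane with a realized kernel.

    The plane is implicitly zero-padded to full support; the output keeps the
    plane's grid.  With a unit-normalized kernel the interior dose integral is
    conserved.
    """
    if abs(plane.spacing - kernel.spacing) > 1e-9 * max(plane.spacing, kernel.spacing):
        raise GridMismatchError(
            f"plane spacing {plane.spacing} != kernel spacing {kernel.spacing}"
        )
    out = fftconvolve(plane.values, kernel.values, mode="same") * plane.spacing**2
    return plane.with_values(np.maximum(out, 0.0))


# -- fitting ---------------------------------------------------------------

def _separable_convolved_cut(positions: np.ndarray, profile: np.ndarray,
                             params: ScatterKernelParams, spacing: float) -> np.ndarray:
    """Central cut of (P ⊗ SK) for a separable square-field plane.

    A square field with isotropic edge blur factorizes as
    P(x, y) = p(x)·p(y)/p(0), which is exact for the calibration fields the
    fit consumes; the 2D convolution is then computed on the outer-product
    plane and cut along y = 0.
    """
    c = int(np.argmin(np.abs(positions)))
    p0 = profile[c]
    if p0 <= 0:
        raise InvalidInputError("profile must be positive at the CAX")
    plane2 = np.outer(profile, profile) / p0
    half_width = min(3.0 * params.max_width, positions[-1] - positions[0])
    ker = kernel_evaluate(params, spacing, half_width=half_width)
    conv = fftconvolve(plane2, ker.values, mode="same") * spacing**2
    return conv[c, :]


def _fit_region(positions: np.ndarray, reference: np.ndarray,
                half_width_factor: float = 1.5,
                tail_fraction: float = 0.005) -> np.ndarray:
    """In-field + penumbra mask, extended over the visible scatter tails.

    The core region is ±factor × the 50% half-width.  Positions where the
    reference still carries more than ``tail_fraction`` of the CAX dose are
    kept as well: for small fields with broad kernels the tails are what pin
    the kernel mass outside the field, without which the fitted kernel's CAX
    action is poorly identified.
    """
    from .evaluation import Profile, field_edges_50

    left, right = field_edges_50(Profile(positions, reference))
    half = half_width_factor * (right - left) / 2.0
    center = (left + right) / 2.0
    c = int(np.argmin(np.abs(positions)))
    core = np.abs(positions - center) <= half
    tails = reference > tail_fraction * reference[c]
    return core | tails


def fit_kernel_single(positions: np.ndarray, unconvolved: np.ndarray,
                      reference: np.ndarray, *,
                      x0=DEFAULT_X0, max_nfev: int = 300) -> tuple[ScatterKernelParams, float]:
    """Fit one kernel so the convolved profile matches the reference shape.

    Both profiles are normalized to their CAX values (the amplitude is owned
    by the scatter correction factor, not the kernel).  Returns the fitted
    parameters and the RMS residual as a fraction of the CAX dose.  The fit
    is deterministic: fixed starting point, bounds and tolerances.
    """
    positions = np.asarray(positions, float)
    unconvolved = np.asarray(unconvolved, float)
    reference = np.asarray(reference, float)
    if positions.shape != unconvolved.shape or positions.shape != reference.shape:
        raise InvalidInputError("profile arrays must share one position grid")
    if positions.size < 5:
        raise InvalidInputError("profiles too short to fit a kernel")
    spacing = float(positions[1] - positions[0])
    if not np.allclose(np.diff(positions), spacing, rtol=1e-6):
        raise InvalidInputError("positions must be uniformly spaced")
    if reference.max() - reference.min() < 1e-12 * max(reference.max(), 1.0):
        raise InvalidInputError("reference profile is flat; nothing to fit")
    c = int(np.argmin(np.abs(positions)))
    mask = _fit_region(positions, reference)
    ref_n = reference / reference[c]

    def residuals(x: np.ndarray) -> np.ndarray:
        params = ScatterKernelParams(*x)
        cut = _separable_convolved_cut(positions, unconvolved, params, spacing)
        return (cut / cut[c] - ref_n)[mask]

    lo = [WIDTH_BOUNDS[0], AMPLITUDE_BOUNDS[0], WIDTH_BOUNDS[0],
          AMPLITUDE_BOUNDS[0], WIDTH_BOUNDS[0]]
    hi = [WIDTH_BOUNDS[1], AMPLITUDE_BOUNDS[1], WIDTH_BOUNDS[1],
          AMPLITUDE_BOUNDS[1], WIDTH_BOUNDS[1]]
    res = least_squares(residuals, np.asarray(x0, float), bounds=(lo, hi),
                        method="trf", xtol=1e-8, ftol=1e-8, gtol=1e-6,
                        max_nfev=max_nfev)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    # the three Gaussians are exchangeable, so the cost surface has flat
    # valleys: hitting the evaluation budget with a tiny residual is
    # convergence in the only sense that matters (the kernel's action)
    if not res.success and rms > 1e-4:
        raise FitFailureError(f"kernel fit did not converge: {res.message}", res)
    return ScatterKernelParams(*res.x), rms


def fit_kernel(unconvolved_profiles, reference_profiles, **kwargs):
    """Fit a kernel for every (field size, depth) pair.

    Each element of both sequences is ``(positions, values, field_size_cm,
    depth_cm)``; pairs are matched positionally and must agree on field size,
    depth and grid.  Returns ``{(fs, depth): (ScatterKernelParams, rms)}``.
    """
    unconvolved = list(unconvolved_profiles)
    reference = list(reference_profiles)
    if len(unconvolved) != len(reference):
        raise InvalidInputError("profile sequences differ in length")
    out: dict[tuple[float, float], tuple[ScatterKernelParams, float]] = {}
    for (pos_u, val_u, fs_u, d_u), (pos_r, val_r, fs_r, d_r) in zip(unconvolved, reference):
        if (fs_u, d_u) != (fs_r, d_r):
            raise InvalidInputError(
                f"mismatched pair: ({fs_u}, {d_u}) vs ({fs_r}, {d_r})"
            )
        if not np.allclose(pos_u, pos_r):
            raise InvalidInputError("paired profiles must share a position grid")
        out[(float(fs_u), float(d_u))] = fit_kernel_single(pos_u, val_u, val_r, **kwargs)
    return out


def kernel_interpolate(table, equivalent_square: float, depth: float) -> ScatterKernelParams:
    """Per-parameter bilinear interpolation in (field size, depth), clamped.

    ``table`` is any object exposing ``field_sizes``, ``depths`` and a
    ``kernel_params`` array of shape (n_fs, n_depth, 5) — in practice a
    :class:`transitdose.scatter.ScatterTables`.
    """
    params = table.kernel_params
    if params is None or np.asarray(params).size == 0:
        raise InvalidInputError("table has no kernel parameters")
    vec = bilinear_clamped(np.asarray(table.field_sizes, float),
                           np.asarray(table.depths, float),
                           np.asarray(params, float),
                           equivalent_square, depth)
    return ScatterKernelParams(*vec)
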