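"""Synthetic forward projector: ground-truth planes and transit fluences
with every parameter known, so the whole reconstruction chain is testable
in a closed loop without measurement data.

Model
-----
The open fluence at distance ``z`` is the aperture projected to ``z``,
edge-blurred by a penumbra Gaussian (σ scales with magnification), times a
reference output and the inverse-square factor ``(100/z)²``.  Behind a slab
the primary is further attenuated by ``exp(−∫μ dz)``.

Two scatter components are generated:

* *detector-plane scatter* — a small, field-size-dependent addition to the
  transit fluence (the air gap rejects most of it): a broad Gaussian blur of
  the primary scaled so that the realized transmission-fraction difference
  TF(fs) − TF(0) at the CAX equals the configured fraction (≤ ~3% at the
  largest fields).
* *in-phantom depth scatter* — the dose at a reconstruction depth exceeds
  the backprojected primary by a factor 1/(1 − s(fs, depth)); ``s`` is the
  scatter-to-total fraction the SCF calibration must recover.

Lateral in-phantom scatter is modeled by convolving the plane with a true
triple-Gaussian kernel whose widths grow with depth.  The ground truth at
depth ``d`` is therefore

    GT(d) = [ primary(d) / (1 − s(fs, d)) ] ⊗ SK_true(fs, d),

which the backprojection pipeline inverts exactly when its tables are
calibrated from the same model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .errors import InvalidInputError, OutOfRangeError
from .geometry import (
    ISOCENTER_CM,
    ApertureMask,
    BeamGeometry,
    equivalent_square,
)
from .kernel import ScatterKernelParams, kernel_evaluate
from .phantom import SlabPhantom
from .plane import DosePlane, write_plane
from .scatter import TransmissionRecord

__all__ = [
    "ForwardModelConfig",
    "default_conformal_aperture",
    "ground_truth_plane",
    "forward_transit",
    "make_transmission_records",
    "CalibrationField",
    "CalibrationSuite",
    "make_calibration_suite",
    "write_suite",
]


# -- default scatter/kernel laws ------------------------------------------

def default_detector_scatter(field_size: float, air_gap: float) -> float:
    """CAX detector-plane scatter fraction (TF-difference sense).

    Linear in the equivalent-square side, ~2.9% at 15 cm, independent of the
    air gap over the 40-60 cm range the model targets.
    """
    return 0.0019 * field_size


def default_depth_scatter(field_size: float, depth: float) -> float:
    """In-phantom scatter-to-total fraction at the reconstruction depth.

    Bilinear in (field size, depth): ≈ 9% for a 5×5 cm² field at 10 cm depth,
    rising to ≈ 30% for 15×15 cm² at 15 cm.
    """
    return (0.05 + 0.010 * field_size) * depth / 10.0


def default_true_kernel(field_size: float, depth: float) -> ScatterKernelParams:
    """Generating lateral-scatter kernel; widths grow linearly with depth."""
    a = 0.1 + 0.06 * depth
    return ScatterKernelParams(A=a, B=0.1, C=2.0 * a, D=0.05, E=3.0 * a)


def default_conformal_aperture(spacing: float = 0.1) -> ApertureMask:
    """Irregular L-shaped conformal segment (equivalent square ≈ 6.5 cm)."""
    return ApertureMask.from_rectangles(
        [(-3.5, -4.0, 1.5, 4.0), (1.5, -4.0, 4.5, 0.0)], spacing=spacing
    )


@dataclass(frozen=True)
class ForwardModelConfig:
    """Everything the forward projector needs, with study-condition defaults.

    The default geometry is the slab validation setup: 20 cm of solid water
    at 90 cm SSD, detector at 160 cm SDD (50 cm air gap), 2 mm working grid
    over 24×24 cm² at the detector, 0.3 cm penumbra sigma at isocenter,
    μ_eff = 0.05 cm⁻¹ and no measurement noise.
    """

    geometry: BeamGeometry = field(
        default_factory=lambda: BeamGeometry(sdd=160.0, spd=100.0, ssd=90.0)
    )
    phantom: SlabPhantom = field(
        default_factory=lambda: SlabPhantom.homogeneous(20.0, 0.05, 90.0)
    )
    aperture: ApertureMask = field(default_factory=lambda: ApertureMask.square(10.0))
    penumbra_sigma: float = 0.3  # cm at isocenter
    detector_scatter: Callable[[float, float], float] = default_detector_scatter
    scatter_blur_sigma: float = 1.5  # cm at the detector plane
    depth_scatter: Callable[[float, float], float] = default_depth_scatter
    true_kernel: Callable[[float, float], ScatterKernelParams] = default_true_kernel
    reference_dose: float = 100.0  # cGy at 100 cm, open CAX
    grid_spacing: float = 0.2  # cm at the detector plane
    grid_half_width: float = 12.0  # cm at the detector plane
    noise_sigma: float = 0.0  # fraction of local dose
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be >= 0")
        if self.penumbra_sigma < 0:
            raise InvalidInputError("penumbra_sigma must be >= 0")
        if not (self.grid_spacing > 0 and self.grid_half_width > 0):
            raise InvalidInputError("grid parameters must be positive")

    @property
    def equivalent_square(self) -> float:
        return equivalent_square(self.aperture)

    def replace(self, **kwargs) -> "ForwardModelConfig":
        return dataclasses.replace(self, **kwargs)


# -- internals -------------------------------------------------------------

def _plane_grid(config: ForwardModelConfig, distance: float) -> tuple[np.ndarray, float]:
    """Grid coordinates at ``distance``: the detector grid projected there,
    so planes at different depths coincide node-for-node after projection."""
    scale = distance / config.geometry.sdd
    spacing = config.grid_spacing * scale
    m = int(np.floor(config.grid_half_width * scale / spacing + 1e-9))
    return spacing * np.arange(-m, m + 1), spacing


def _aperture_fluence(config: ForwardModelConfig, distance: float,
                      extra_sigma: float = 0.0) -> DosePlane:
    """Aperture projected to ``distance`` and blurred by the penumbra (and
    optionally an extra in-quadrature sigma), unit plateau."""
    coords, spacing = _plane_grid(config, distance)
    scale = distance / ISOCENTER_CM
    ap = config.aperture
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator((ap.y, ap.x), ap.values,
                                     bounds_error=False, fill_value=0.0)
    gy, gx = np.meshgrid(coords / scale, coords / scale, indexing="ij")
    mask = interp(np.stack([gy, gx], axis=-1))
    sigma = np.hypot(config.penumbra_sigma * scale, extra_sigma)
    if sigma > 0:
        mask = gaussian_filter(mask, sigma / spacing, mode="constant", truncate=6.0)
    return DosePlane(mask, spacing, (coords[0], coords[0]), source_distance=distance)


def _primary_plane(config: ForwardModelConfig, distance: float,
                   depth_in_phantom: float | None) -> DosePlane:
    """Primary fluence at ``distance``; ``depth_in_phantom`` sets the
    attenuation integral (None = no slab in the beam)."""
    fluence = _aperture_fluence(config, distance)
    out = config.reference_dose * (ISOCENTER_CM / distance) ** 2
    if depth_in_phantom is not None:
        out *= np.exp(-config.phantom.attenuation_between(0.0, depth_in_phantom))
    return fluence.with_values(fluence.values * out)


# -- public forward operations --------------------------------------------

def ground_truth_plane(config: ForwardModelConfig, depth: float) -> DosePlane:
    """True total dose plane at ``depth`` cm inside the phantom."""
    t = config.phantom.thickness
    if not (-1e-12 <= depth <= t + 1e-12):
        raise OutOfRangeError(f"depth {depth} outside phantom [0, {t}]")
    depth = min(max(depth, 0.0), t)
    spd = config.phantom.ssd + depth
    primary = _primary_plane(config, spd, depth_in_phantom=depth)
    fs = config.equivalent_square
    s = config.depth_scatter(fs, depth)
    if not 0.0 <= s < 1.0:
        raise InvalidInputError(f"depth scatter fraction {s} outside [0, 1)")
    vals = primary.values / (1.0 - s)
    params = config.true_kernel(fs, depth)
    ker = kernel_evaluate(params, primary.spacing)
    vals = fftconvolve(vals, ker.values, mode="same") * primary.spacing**2
    return primary.with_values(np.maximum(vals, 0.0))


def forward_transit(config: ForwardModelConfig, *, with_slab: bool = True,
                    with_scatter: bool = True) -> DosePlane:
    """Transit fluence at the detector plane.

    With the slab in place the primary is fully attenuated and a broad,
    field-size-dependent scatter component is added; the amplitude is scaled
    by 1/TF(0) so the realized CAX transmission-fraction difference equals
    the configured detector scatter fraction.  Multiplicative Gaussian noise
    (``noise_sigma`` as a fraction of local dose, seeded) models detector
    reproducibility.
    """
    sdd = config.geometry.sdd
    t = config.phantom.thickness
    primary = _primary_plane(config, sdd, depth_in_phantom=t if with_slab else None)
    vals = primary.values.copy()
    if with_slab and with_scatter:
        gap = config.geometry.air_gap(t)
        fs = config.equivalent_square
        sf = config.detector_scatter(fs, gap)
        if sf < 0:
            raise InvalidInputError("detector scatter fraction must be >= 0")
        if sf > 0:
            tf0 = np.exp(-config.phantom.attenuation_between(0.0, t))
            blurred = gaussian_filter(vals, config.scatter_blur_sigma / primary.spacing,
                                      mode="constant", truncate=6.0)
            vals = vals + (sf / tf0) * blurred
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        vals = vals * (1.0 + config.noise_sigma * rng.standard_normal(vals.shape))
    return primary.with_values(np.maximum(vals, 0.0))


def make_transmission_records(config: ForwardModelConfig, field_sizes,
                              air_gaps) -> list[TransmissionRecord]:
    """CAX transit doses with and without the slab for a scatter study.

    For each air gap the detector is moved to ``ssd + thickness + gap``;
    noise is disabled so the records characterize the model itself.
    """
    records = []
    t = config.phantom.thickness
    for gap in air_gaps:
        sdd = config.phantom.ssd + t + gap
        geo = dataclasses.replace(config.geometry, sdd=sdd, spd=min(config.geometry.spd, sdd))
        for fs in field_sizes:
            cfg = config.replace(
                geometry=geo,
                aperture=ApertureMask.square(float(fs), spacing=config.aperture.spacing),
                noise_sigma=0.0,
            )
            with_slab = forward_transit(cfg, with_slab=True).cax()
            open_field = forward_transit(cfg, with_slab=False).cax()
            records.append(TransmissionRecord(float(fs), float(gap), with_slab, open_field))
    return records


# -- calibration suite -----------------------------------------------------

@dataclass(frozen=True)
class CalibrationField:
    """One square calibration field: transit plane + per-depth ground truth."""

    field_size: float
    aperture: ApertureMask
    geometry: BeamGeometry
    phantom: SlabPhantom
    transit: DosePlane
    ground_truth: dict[float, DosePlane]


@dataclass(frozen=True)
class CalibrationSuite:
    fields: tuple[CalibrationField, ...]
    depths: tuple[float, ...]
    config: ForwardModelConfig


def make_calibration_suite(config: ForwardModelConfig,
                           field_sizes=(3.0, 5.0, 10.0),
                           depths=(2.0, 6.0, 10.0, 15.0)) -> CalibrationSuite:
    """Matched (transit, ground-truth) bundles for square calibration fields.

    The field-size set mirrors the calibration measurements (3×3, 5×5 and
    10×10 cm²); depths span the reconstruction range so kernel and SCF
    tables interpolate rather than extrapolate.
    """
    fields = []
    for fs in field_sizes:
        cfg = config.replace(
            aperture=ApertureMask.square(float(fs), spacing=config.aperture.spacing)
        )
        transit = forward_transit(cfg)
        gt = {float(d): ground_truth_plane(cfg, float(d)) for d in depths}
        fields.append(CalibrationField(float(fs), cfg.aperture, cfg.geometry,
                                       cfg.phantom, transit, gt))
    return CalibrationSuite(tuple(fields), tuple(float(d) for d in depths), config)


def write_suite(suite: CalibrationSuite, directory) -> None:
    """Write the suite as plane CSVs plus a JSON manifest of true parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "depths_cm": list(suite.depths),
        "reference_dose_cgy": suite.config.reference_dose,
        "penumbra_sigma_cm": suite.config.penumbra_sigma,
        "noise_sigma": suite.config.noise_sigma,
        "seed": suite.config.seed,
        "fields": [],
    }
    for f in suite.fields:
        tag = f"fs{f.field_size:g}"
        write_plane(f.transit, directory / f"transit_{tag}.csv")
        for d, plane in f.ground_truth.items():
            write_plane(plane, directory / f"truth_{tag}_d{d:g}.csv")
        manifest["fields"].append({
            "field_size_cm": f.field_size,
            "sdd_cm": f.geometry.sdd,
            "ssd_cm": f.phantom.ssd,
            "thickness_cm": f.phantom.thickness,
            "depth_scatter": {f"{d:g}": suite.config.depth_scatter(f.field_size, d)
                              for d in suite.depths},
            "detector_scatter": suite.config.detector_scatter(
                f.field_size, f.geometry.air_gap(f.phantom.thickness)),
        })
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
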