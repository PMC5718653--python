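"""Scatter characterization: transmission fractions, the zero-field-size
extrapolation, and the scatter correction factor (SCF).

Two distinct scatter quantities live here.  The *detector-plane* scatter
fraction is measured by the transmission-fraction method: the ratio of CAX
transit dose with and without the slab, extrapolated linearly in equivalent
square down to zero field size, isolates the primary transmission; the
excess at a finite field size is the scatter fraction.  The *SCF* is the
calibration-time ratio (total − backprojected)/total at the reconstruction
plane; it restores the in-phantom scatter the primary backprojection misses,
and is applied multiplicatively at reconstruction time as 1/(1 − SCF).
Collimator and phantom scatter are merged in a single factor, one value per
segment, evaluated at the segment's equivalent square and depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidCalibrationError,
    InvalidInputError,
)
from .geometry import ApertureMask, BeamGeometry, equivalent_square, iscf, project_plane
from .kernel import ScatterKernelParams, convolve, kernel_evaluate, kernel_interpolate
from .phantom import SlabPhantom, acf, radiological_path
from .plane import DosePlane, bilinear_clamped

__all__ = [
    "TransmissionRecord",
    "ScatterTables",
    "CalibrationEntry",
    "transmission_fraction",
    "scatter_fraction_extrapolate",
    "backproject_primary",
    "estimate_scf",
    "scf_lookup",
]


@dataclass(frozen=True)
class TransmissionRecord:
    """CAX doses with/without the slab for one field size and air gap."""

    field_size: float
    air_gap: float
    dose_with_slab: float
    dose_open: float

    def __post_init__(self) -> None:
        if self.dose_open <= 0:
            raise InvalidInputError("open-field dose must be positive")
        if self.dose_with_slab <= 0:
            raise InvalidInputError("with-slab dose must be positive")


def transmission_fraction(record: TransmissionRecord) -> float:
    """Ratio of the with-slab to open CAX transit dose."""
    return record.dose_with_slab / record.dose_open


def scatter_fraction_extrapolate(records) -> dict[float, float]:
    """Scatter fraction per field size from the zero-field-size extrapolation.

    Fits a straight line to transmission fraction vs equivalent-square side
    (the field-size growth is near linear), extrapolates to zero field size
    to isolate the primary transmission TF(0), and returns
    ``SF(fs) = TF(fs) − TF(0)`` for each input field size.  All records must
    share one air gap.
    """
    records = list(records)
    fs = np.array([r.field_size for r in records], float)
    if np.unique(fs).size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct field sizes, got {np.unique(fs).size}"
        )
    gaps = {round(r.air_gap, 6) for r in records}
    if len(gaps) != 1:
        raise InvalidInputError(f"records mix air gaps {sorted(gaps)}")
    tf = np.array([transmission_fraction(r) for r in records])
    slope, intercept = np.polyfit(fs, tf, 1)
    sf = {float(f): float(t - intercept) for f, t in zip(fs, tf)}
    if slope < 0 or any(v < -1e-6 for v in sf.values()):
        warnings.warn(
            "transmission fraction decreases with field size; "
            "extrapolated scatter fractions may be unreliable",
            UserWarning,
            stacklevel=2,
        )
    return sf


@dataclass(frozen=True)
class ScatterTables:
    """SCF and kernel-parameter lookup keyed by (equivalent square, depth).

    ``scf`` has shape (n_fs, n_depth); ``kernel_params`` (n_fs, n_depth, 5)
    ordered (A, B, C, D, E), or ``None`` when reconstruction should skip the
    convolution (identity kernel).  Lookups interpolate bilinearly and clamp
    at the table edges.
    """

    field_sizes: np.ndarray
    depths: np.ndarray
    scf: np.ndarray
    kernel_params: np.ndarray | None = None
    kernel_rms: np.ndarray | None = None

    def __post_init__(self) -> None:
        fs = np.asarray(self.field_sizes, float)
        dp = np.asarray(self.depths, float)
        scf = np.asarray(self.scf, float)
        if scf.shape != (fs.size, dp.size):
            raise InvalidInputError(
                f"scf shape {scf.shape} != ({fs.size}, {dp.size})"
            )
        if np.any(np.diff(fs) <= 0) or np.any(np.diff(dp) <= 0):
            raise InvalidInputError("field sizes and depths must be strictly increasing")
        if np.any(scf >= 1.0):
            raise InvalidCalibrationError("SCF >= 1 would invert to a non-positive total")
        object.__setattr__(self, "field_sizes", fs)
        object.__setattr__(self, "depths", dp)
        object.__setattr__(self, "scf", scf)
        if self.kernel_params is not None:
            kp = np.asarray(self.kernel_params, float)
            if kp.shape != (fs.size, dp.size, 5):
                raise InvalidInputError("kernel_params must have shape (n_fs, n_depth, 5)")
            object.__setattr__(self, "kernel_params", kp)

    @classmethod
    def zero(cls, field_sizes=(3.0, 10.0), depths=(0.0, 20.0)) -> "ScatterTables":
        """Tables with SCF = 0 everywhere and no kernel (identity convolution)."""
        fs = np.asarray(field_sizes, float)
        dp = np.asarray(depths, float)
        return cls(fs, dp, np.zeros((fs.size, dp.size)), None)

    def scf_at(self, equivalent_square: float, depth: float) -> float:
        return float(bilinear_clamped(self.field_sizes, self.depths, self.scf,
                                      equivalent_square, depth))

    def kernel_at(self, equivalent_square: float, depth: float) -> ScatterKernelParams | None:
        if self.kernel_params is None:
            return None
        return kernel_interpolate(self, equivalent_square, depth)

    # -- plain-text serialization -----------------------------------------
    def write_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fs_grid, d_grid = np.meshgrid(self.field_sizes, self.depths, indexing="ij")
        pd.DataFrame({
            "field_size_cm": fs_grid.ravel(),
            "depth_cm": d_grid.ravel(),
            "scf": self.scf.ravel(),
        }).to_csv(directory / "scf.csv", index=False)
        if self.kernel_params is not None:
            cols = {"field_size_cm": fs_grid.ravel(), "depth_cm": d_grid.ravel()}
            for k, name in enumerate("ABCDE"):
                cols[name] = self.kernel_params[:, :, k].ravel()
            if self.kernel_rms is not None:
                cols["rms_residual"] = np.asarray(self.kernel_rms).ravel()
            pd.DataFrame(cols).to_csv(directory / "kernel.csv", index=False)

    @classmethod
    def read_dir(cls, directory) -> "ScatterTables":
        directory = Path(directory)
        scf_df = pd.read_csv(directory / "scf.csv")
        fs = np.unique(scf_df["field_size_cm"].to_numpy())
        dp = np.unique(scf_df["depth_cm"].to_numpy())
        scf = (scf_df.sort_values(["field_size_cm", "depth_cm"])["scf"]
               .to_numpy().reshape(fs.size, dp.size))
        kp = None
        rms = None
        kpath = directory / "kernel.csv"
        if kpath.exists():
            kdf = pd.read_csv(kpath).sort_values(["field_size_cm", "depth_cm"])
            kp = np.stack([kdf[name].to_numpy().reshape(fs.size, dp.size)
                           for name in "ABCDE"], axis=-1)
            if "rms_residual" in kdf:
                rms = kdf["rms_residual"].to_numpy().reshape(fs.size, dp.size)
        return cls(fs, dp, scf, kp, rms)


def scf_lookup(tables: ScatterTables, equivalent_square: float, depth: float) -> float:
    """Bilinear SCF lookup, clamped to the nearest edge outside the table."""
    return tables.scf_at(equivalent_square, depth)


# -- SCF estimation --------------------------------------------------------

@dataclass(frozen=True)
class CalibrationEntry:
    """One calibration field: transit plane + known total dose at a depth."""

    transit: DosePlane
    aperture: ApertureMask
    geometry: BeamGeometry
    phantom: SlabPhantom
    total: DosePlane
    depth: float


def backproject_primary(transit: DosePlane, geometry: BeamGeometry,
                        phantom: SlabPhantom, depth: float) -> DosePlane:
    """Transit plane projected to the reconstruction plane and scaled by
    ISCF·ACF — the primary-dose backprojection before any scatter handling."""
    spd = phantom.ssd + depth
    geo = geometry.with_spd(spd)
    plane = project_plane(transit, geometry.sdd, spd)
    _, exponent = radiological_path(phantom, geo, depth)
    factor = iscf(geo) * acf(exponent)
    return plane.with_values(plane.values * factor)


def estimate_scf(calibration, kernel_table=None) -> ScatterTables:
    """Build the SCF table from calibration fields with known total doses.

    For each entry the transit plane is backprojected (ISCF·ACF), convolved
    with the fitted scatter kernel when ``kernel_table`` provides one, and
    compared with the known total at the CAX:

        SCF = (total − backprojected) / total.

    Including the kernel keeps the calibration self-consistent: dividing the
    backprojection by (1 − SCF) and convolving reproduces the calibration
    totals exactly at the table nodes.  Entries must form a full
    (field size × depth) factorial.
    """
    entries = list(calibration)
    if not entries:
        raise InvalidCalibrationError("no calibration entries")
    rows = []
    for e in entries:
        eqsq = equivalent_square(e.aperture)
        total_cax = e.total.cax()
        if total_cax <= 0:
            raise InvalidCalibrationError(
                f"total dose at CAX must be positive (fs={eqsq:.3g}, depth={e.depth})"
            )
        bp = backproject_primary(e.transit, e.geometry, e.phantom, e.depth)
        if kernel_table is not None and kernel_table.kernel_params is not None:
            params = kernel_interpolate(kernel_table, eqsq, e.depth)
            bp = convolve(bp, kernel_evaluate(params, bp.spacing))
        scf_val = (total_cax - bp.cax()) / total_cax
        rows.append((round(eqsq, 9), float(e.depth), scf_val))
    fs = np.unique([r[0] for r in rows])
    dp = np.unique([r[1] for r in rows])
    scf = np.full((fs.size, dp.size), np.nan)
    for f, d, v in rows:
        scf[np.searchsorted(fs, f), np.searchsorted(dp, d)] = v
    if np.isnan(scf).any():
        raise InvalidCalibrationError(
            "calibration entries do not form a full field-size × depth grid"
        )
    kp = getattr(kernel_table, "kernel_params", None)
    rms = getattr(kernel_table, "kernel_rms", None)
    if kp is not None:
        kt_fs = np.asarray(kernel_table.field_sizes, float)
        kt_dp = np.asarray(kernel_table.depths, float)
        if kt_fs.shape != fs.shape or kt_dp.shape != dp.shape or \
                not (np.allclose(kt_fs, fs) and np.allclose(kt_dp, dp)):
            # keep SCF grid; re-interpolate kernels onto it
            kp = np.stack([
                [kernel_interpolate(kernel_table, f, d).as_array() for d in dp]
                for f in fs
            ])
            rms = None
    return ScatterTables(fs, dp, scf, kp, rms)
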