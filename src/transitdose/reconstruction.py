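"""The backprojection pipeline: per-segment reconstruction, segment
summation, depth-dose extraction.

One segment reconstructs as

    D_recon(depth) = [ D_transit → project to SPD → ·ISCF·ACF ] / (1 − SCF) ⊗ SK

where ISCF = (SDD/SPD)² undoes divergence, ACF = e^{Σμℓ} undoes attenuation
between the plane and the detector, SCF (from the calibration tables,
looked up at the segment's equivalent square and depth) restores the
in-phantom scatter the primary backprojection misses, and SK is the fitted
lateral-scatter kernel interpolated at the same key.  Intensity-modulated
fields are handled segment by segment and summed afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError, InvalidInputError
from .geometry import ApertureMask, BeamGeometry, equivalent_square
from .kernel import convolve, kernel_evaluate
from .phantom import SlabPhantom
from .plane import DosePlane, read_plane, write_plane  # noqa: F401  (re-export)
from .scatter import backproject_primary

if TYPE_CHECKING:  # pragma: no cover
    from .scatter import ScatterTables

__all__ = [
    "DosePlane",
    "Segment",
    "reconstruct",
    "reconstruction_factors",
    "sum_segments",
    "depth_dose_curve",
    "read_plane",
    "write_plane",
]


@dataclass(frozen=True)
class Segment:
    """One deliverable aperture with its measured transit plane."""

    aperture: ApertureMask
    transit: DosePlane
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise InvalidInputError("segment MU must be >= 0")
        if np.any(self.transit.values < 0):
            raise InvalidInputError("transit plane must be non-negative")
        if np.any(~np.isfinite(self.transit.values)):
            raise InvalidInputError(
                "transit plane has missing values; fill them before reconstruction"
            )


def reconstruction_factors(segment: Segment, geometry: BeamGeometry,
                           phantom: SlabPhantom, tables: "ScatterTables",
                           depth: float) -> dict:
    """The correction factors a reconstruction at this depth will apply.

    Returned for logging/audit: equivalent square, SPD, ISCF, attenuation
    exponent, SCF and the interpolated kernel parameters.
    """
    from .geometry import iscf as _iscf
    from .phantom import radiological_path

    eqsq = equivalent_square(segment.aperture)
    spd = phantom.ssd + depth
    geo = geometry.with_spd(spd)
    _, exponent = radiological_path(phantom, geo, depth)
    params = tables.kernel_at(eqsq, depth)
    return {
        "equivalent_square_cm": eqsq,
        "depth_cm": depth,
        "spd_cm": spd,
        "iscf": _iscf(geo),
        "acf_exponent": exponent,
        "scf": tables.scf_at(eqsq, depth),
        "kernel": None if params is None else params.as_array().tolist(),
    }


def reconstruct(segment: Segment, geometry: BeamGeometry, phantom: SlabPhantom,
                tables: "ScatterTables", depth: float) -> DosePlane:
    """Reconstruct the dose plane at ``depth`` cm inside the phantom."""
    eqsq = equivalent_square(segment.aperture)
    bp = backproject_primary(segment.transit, geometry, phantom, depth)
    scf = tables.scf_at(eqsq, depth)
    if not scf < 1.0:
        raise InvalidInputError(f"SCF {scf} >= 1 at fs={eqsq:.3g}, depth={depth}")
    out = bp.with_values(bp.values / (1.0 - scf))
    params = tables.kernel_at(eqsq, depth)
    if params is not None:
        out = convolve(out, kernel_evaluate(params, out.spacing))
    return out.with_values(np.maximum(out.values, 0.0))


def sum_segments(planes: Sequence[DosePlane]) -> DosePlane:
    """Cell-wise sum of per-segment reconstructions on identical grids."""
    planes = list(planes)
    if not planes:
        raise InvalidInputError("no planes to sum")
    first = planes[0]
    total = np.zeros_like(first.values)
    for p in planes:
        first.require_matching(p)
        sd_a, sd_b = first.source_distance, p.source_distance
        if sd_a is not None and sd_b is not None and abs(sd_a - sd_b) > 1e-9:
            raise GridMismatchError("segment planes lie at different source distances")
        total = total + p.values
    return first.with_values(total)


def depth_dose_curve(segment: Segment, geometry: BeamGeometry,
                     phantom: SlabPhantom, tables: "ScatterTables",
                     depths) -> pd.DataFrame:
    """CAX dose of the reconstructed plane at each depth.

    Returns a DataFrame with columns ``depth_cm`` and ``cax_dose_cgy``.
    """
    rows = []
    for d in depths:
        plane = reconstruct(segment, geometry, phantom, tables, float(d))
        rows.append((float(d), plane.cax()))
    return pd.DataFrame(rows, columns=["depth_cm", "cax_dose_cgy"])
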