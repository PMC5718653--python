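"""Beam geometry: distances, divergence, apertures and the equivalent square.

All distances are in cm.  Field sizes and aperture masks are defined in the
isocenter plane, 100 cm from the source, and scaled geometrically to other
planes.  The inverse-square correction factor (ISCF) converts fluence
measured at the detector distance (SDD) to the reconstruction-plane distance
(SPD):

    ISCF = (SDD / SPD)**2
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateApertureError, InvalidGeometryError, InvalidInputError
from .plane import DosePlane

ISOCENTER_CM = 100.0

__all__ = ["BeamGeometry", "ApertureMask", "iscf", "equivalent_square", "project_plane"]


@dataclass(frozen=True)
class BeamGeometry:
    """Source/detector/plane distances plus delivery metadata.

    ``sdd``: source-to-detector distance; ``spd``: source-to-plane distance of
    the reconstruction plane; ``ssd``: source-to-phantom-surface distance.
    ``field_size`` is the (x, y) field size at 100 cm; ``mu`` the delivered
    monitor units (metadata only — planes are absolute dose).
    """

    sdd: float
    spd: float
    ssd: float
    field_size: tuple[float, float] | None = None
    mu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sdd", "spd", "ssd"):
            if not getattr(self, name) > 0:
                raise InvalidGeometryError(f"{name} must be positive, got {getattr(self, name)}")
        if self.spd > self.sdd + 1e-12:
            raise InvalidGeometryError(
                f"reconstruction plane (spd={self.spd}) lies beyond the detector (sdd={self.sdd})"
            )
        if self.mu < 0:
            raise InvalidGeometryError(f"mu must be >= 0, got {self.mu}")

    def air_gap(self, phantom_thickness: float) -> float:
        """Exit-surface-to-detector distance for a slab of the given thickness."""
        gap = self.sdd - (self.ssd + phantom_thickness)
        if gap < -1e-9:
            raise InvalidGeometryError(
                f"phantom (ssd={self.ssd} + t={phantom_thickness}) extends past the detector"
            )
        return max(gap, 0.0)

    def with_spd(self, spd: float) -> "BeamGeometry":
        return dataclasses.replace(self, spd=spd)


@dataclass(frozen=True)
class ApertureMask:
    """Fractional open-area grid in the isocenter plane.

    ``values[i, j]`` in [0, 1] is the open fraction of the cell centered at
    ``(origin[0] + j*spacing, origin[1] + i*spacing)`` cm at 100 cm from the
    source.
    """

    values: np.ndarray
    spacing: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise InvalidInputError("aperture values must be 2D")
        if not self.spacing > 0:
            raise InvalidInputError("aperture spacing must be positive")
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise InvalidInputError("aperture open fractions must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(vals, 0.0, 1.0))
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing * np.arange(self.values.shape[0])

    def open_area(self) -> float:
        """Open area in cm² at the isocenter plane."""
        return float(self.values.sum()) * self.spacing**2

    @classmethod
    def from_rectangles(cls, rectangles, spacing: float = 0.1,
                        half_width: float | None = None) -> "ApertureMask":
        """Rasterize a union of non-overlapping axis-aligned rectangles.

        ``rectangles`` is an iterable of (x0, y0, x1, y1) in cm at isocenter.
        Partial cells get their analytic overlap fraction; because rectangles
        may not overlap, per-rectangle fractions add (clipped at 1 for safety).
        """
        rects = [tuple(map(float, r)) for r in rectangles]
        if not rects:
            raise DegenerateApertureError("no rectangles supplied")
        if half_width is None:
            half_width = max(max(abs(v) for v in r) for r in rects) + 2 * spacing
        # cell *boundaries* on multiples of the spacing, so rectangles whose
        # edges align with the raster are reproduced exactly
        m = int(np.ceil(half_width / spacing))
        centers = spacing * (np.arange(-m, m) + 0.5)
        lo = centers - spacing / 2
        hi = centers + spacing / 2
        vals = np.zeros((centers.size, centers.size))
        for (x0, y0, x1, y1) in rects:
            if not (x1 > x0 and y1 > y0):
                raise InvalidInputError(f"degenerate rectangle {(x0, y0, x1, y1)}")
            cov_x = np.clip((np.minimum(hi, x1) - np.maximum(lo, x0)) / spacing, 0.0, 1.0)
            cov_y = np.clip((np.minimum(hi, y1) - np.maximum(lo, y0)) / spacing, 0.0, 1.0)
            vals += np.outer(cov_y, cov_x)
        return cls(np.clip(vals, 0.0, 1.0), spacing, (centers[0], centers[0]))

    @classmethod
    def square(cls, side: float, spacing: float = 0.1) -> "ApertureMask":
        """Square field of the given side (cm at isocenter), centered on the CAX."""
        h = side / 2.0
        return cls.from_rectangles([(-h, -h, h, h)], spacing=spacing)


def iscf(geometry: BeamGeometry) -> float:
    """Inverse-square correction factor (SDD/SPD)²."""
    return (geometry.sdd / geometry.spd) ** 2


def equivalent_square(aperture: ApertureMask) -> float:
    """Equivalent-square side 4·A/P of the rasterized open region, cm.

    Area uses the fractional open cells; the perimeter marches the boundary
    of the >= 0.5 binarized mask at mask resolution, so rectilinear apertures
    rasterized on cell boundaries are exact.
    """
    area = aperture.open_area()
    if area <= 0:
        raise DegenerateApertureError("aperture has no open area")
    binary = (aperture.values >= 0.5).astype(np.int8)
    if binary.sum() == 0:
        raise DegenerateApertureError("aperture open fraction everywhere < 0.5")
    padded = np.pad(binary, 1)
    edges = (np.abs(np.diff(padded, axis=0)).sum()
             + np.abs(np.diff(padded, axis=1)).sum())
    perimeter = float(edges) * aperture.spacing
    return 4.0 * area / perimeter


def project_plane(plane: DosePlane, from_distance: float, to_distance: float) -> DosePlane:
    """Geometric magnification of a plane between two source distances.

    Grid coordinates scale by ``to/from``; values are untouched (the
    intensity change belongs to :func:`iscf`).
    """
    if not (from_distance > 0 and to_distance > 0):
        raise InvalidGeometryError("projection distances must be positive")
    s = to_distance / from_distance
    return DosePlane(
        plane.values.copy(),
        plane.spacing * s,
        (plane.origin[0] * s, plane.origin[1] * s),
        source_distance=to_distance,
    )
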