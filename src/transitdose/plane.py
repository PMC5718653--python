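"""2D dose planes on regular grids — the currency every pipeline stage trades in.

A :class:`DosePlane` is a rectangular grid of dose values (cGy) with a grid
spacing (cm), the beam's-eye-view coordinate of its corner cell, and the
distance from the radiation source to the plane.  Coordinates follow the
beam's-eye view with the origin on the central axis (CAX): x is cross-plane
(columns), y is in-plane (rows).  ``values[i, j]`` sits at
``(origin[0] + j*spacing, origin[1] + i*spacing)``.

Planes serialize to a plain-text CSV with a commented header so that every
intermediate artifact of a run remains human-inspectable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import GridMismatchError, InvalidInputError

__all__ = [
    "DosePlane",
    "centered_coords",
    "centered_plane",
    "read_plane",
    "write_plane",
    "bilinear_clamped",
]


@dataclass(frozen=True)
class DosePlane:
    """Regular 2D dose grid with geometry metadata.

    Parameters
    ----------
    values : (ny, nx) array of dose in cGy (non-negative for physical doses).
    spacing : grid spacing in cm (> 0); square cells.
    origin : (x, y) position in cm of ``values[0, 0]`` relative to the CAX.
    source_distance : distance in cm from the source to this plane, or
        ``None`` for planes without beam geometry (e.g. kernel realizations).
    """

    values: np.ndarray
    spacing: float
    origin: tuple[float, float]
    source_distance: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise InvalidInputError("plane values must be a 2D array")
        if not self.spacing > 0:
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    # -- coordinates -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x(self) -> np.ndarray:
        """Cross-plane coordinates of the columns, cm."""
        return self.origin[0] + self.spacing * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        """In-plane coordinates of the rows, cm."""
        return self.origin[1] + self.spacing * np.arange(self.values.shape[0])

    # -- sampling ----------------------------------------------------------
    def sample(self, x, y):
        """Bilinear sample at (x, y) cm; zero outside the grid."""
        interp = RegularGridInterpolator(
            (self.y, self.x), self.values, bounds_error=False, fill_value=0.0
        )
        ya, xa = np.broadcast_arrays(np.asarray(y, float), np.asarray(x, float))
        out = interp(np.stack([ya, xa], axis=-1))
        if np.ndim(y) == 0 and np.ndim(x) == 0:
            return float(out.reshape(-1)[0])
        return out

    def cax(self) -> float:
        """Dose at the central axis (0, 0) by bilinear interpolation."""
        return float(self.sample(0.0, 0.0))

    def central_profile(self, axis: str = "x") -> tuple[np.ndarray, np.ndarray]:
        """Cut through the row/column nearest the CAX.

        Returns (positions, doses).  ``axis='x'`` gives the cross-plane cut.
        """
        if axis == "x":
            i = int(np.argmin(np.abs(self.y)))
            return self.x.copy(), self.values[i, :].copy()
        if axis == "y":
            j = int(np.argmin(np.abs(self.x)))
            return self.y.copy(), self.values[:, j].copy()
        raise InvalidInputError(f"axis must be 'x' or 'y', got {axis!r}")

    # -- bookkeeping -------------------------------------------------------
    def with_values(self, values: np.ndarray) -> "DosePlane":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))

    def grids_match(self, other: "DosePlane", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.spacing - other.spacing) <= tol * max(1.0, self.spacing)
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def require_matching(self, other: "DosePlane", tol: float = 1e-9) -> None:
        if not self.grids_match(other, tol=tol):
            raise GridMismatchError(
                f"grids differ: {self.shape}@{self.spacing:.6g}{self.origin} vs "
                f"{other.shape}@{other.spacing:.6g}{other.origin}"
            )


def centered_coords(half_width: float, spacing: float) -> np.ndarray:
    """Symmetric coordinate vector containing 0 exactly, spanning >= ±half_width."""
    m = int(np.floor(half_width / spacing + 1e-9))
    return spacing * np.arange(-m, m + 1)


def centered_plane(half_width: float, spacing: float,
                   source_distance: float | None = None) -> DosePlane:
    """All-zero square plane centered on the CAX."""
    c = centered_coords(half_width, spacing)
    n = c.size
    return DosePlane(np.zeros((n, n)), spacing, (c[0], c[0]), source_distance)


# -- plain-text I/O --------------------------------------------------------

def write_plane(plane: DosePlane, path) -> None:
    """Write the plane-grid CSV: commented header then the row-major matrix."""
    with open(path, "w") as fh:
        fh.write(f"# spacing_cm: {plane.spacing!r}\n")
        fh.write(f"# origin_x_cm: {plane.origin[0]!r}\n")
        fh.write(f"# origin_y_cm: {plane.origin[1]!r}\n")
        sd = plane.source_distance
        fh.write(f"# source_distance_cm: {'' if sd is None else repr(sd)}\n")
        np.savetxt(fh, plane.values, delimiter=",", fmt="%.10g")


def read_plane(path, *, spacing: float | None = None,
               origin: tuple[float, float] | None = None,
               source_distance: float | None = None) -> DosePlane:
    """Read a plane-grid CSV.

    Headerless matrix CSVs are accepted when ``spacing`` (and optionally
    ``origin``) is supplied; the origin then defaults to centering the grid
    on the CAX.
    """
    header: dict[str, float] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                val = val.strip()
                if val:
                    header[key.strip()] = float(val)
                continue
            rows.append(line)
    values = np.array([[float(tok) for tok in r.split(",")] for r in rows])
    if "spacing_cm" in header:
        spacing = header["spacing_cm"]
        origin = (header["origin_x_cm"], header["origin_y_cm"])
        source_distance = header.get("source_distance_cm", source_distance)
    if spacing is None:
        raise InvalidInputError(f"{path}: no header and no spacing supplied")
    if origin is None:
        ny, nx = values.shape
        origin = (-spacing * (nx - 1) / 2.0, -spacing * (ny - 1) / 2.0)
    return DosePlane(values, spacing, origin, source_distance)


# -- shared table interpolation -------------------------------------------

def bilinear_clamped(xg: np.ndarray, yg: np.ndarray, table: np.ndarray,
                     x: float, y: float) -> np.ndarray:
    """Bilinear interpolation on a rectangular table, clamped at the edges.

    ``table`` has shape (len(xg), len(yg), ...); queries outside the grid
    return the nearest-edge value.  Degenerate single-node axes are allowed.
    """
    xg = np.asarray(xg, float)
    yg = np.asarray(yg, float)
    x = float(np.clip(x, xg[0], xg[-1]))
    y = float(np.clip(y, yg[0], yg[-1]))

    def _bracket(g: np.ndarray, v: float) -> tuple[int, int, float]:
        if g.size == 1:
            return 0, 0, 0.0
        i = int(np.searchsorted(g, v, side="right") - 1)
        i = min(max(i, 0), g.size - 2)
        t = (v - g[i]) / (g[i + 1] - g[i])
        return i, i + 1, t

    i0, i1, tx = _bracket(xg, x)
    j0, j1, ty = _bracket(yg, y)
    return ((1 - tx) * (1 - ty) * table[i0, j0]
            + tx * (1 - ty) * table[i1, j0]
            + (1 - tx) * ty * table[i0, j1]
            + tx * ty * table[i1, j1])
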