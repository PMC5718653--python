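"""Diode-array layout, stepper-translated sampling and film fill-in.

The default layout mimics a 445-diode 22×22 cm² array: the central
10×10 cm² holds 221 diodes on a 1.0 cm within-row pitch with successive
rows shifted 0.5 cm (0.707 cm diagonal spacing); the outer region holds 224
diodes on a 2.0 cm pitch with 1 cm row shifts, including a short transition
ring between the two densities.  A motorized stepper translates the array
cross-plane in 2 mm steps so the union of shifted diode positions fills a
2 mm working grid; cells no shifted diode reaches stay flagged as missing
and are filled in from a film measurement of the same setup.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoverageError, IncompleteFillerError, InvalidInputError
from .plane import DosePlane

__all__ = [
    "DetectorLayout",
    "SampledPlane",
    "build_default_layout",
    "sample_with_stepper",
    "fill_missing",
]


@dataclass(frozen=True)
class DetectorLayout:
    """Diode positions (N, 2) in cm in the detector plane + active area."""

    positions: np.ndarray
    active_area: float = 0.08  # cm, side of the square active area

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise InvalidInputError("positions must be an (N, 2) array")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def central_mask(self, half: float = 5.0) -> np.ndarray:
        """Boolean mask of diodes inside the central ``2·half`` cm square."""
        return np.all(np.abs(self.positions) <= half + 1e-9, axis=1)

    def write_csv(self, path) -> None:
        pd.DataFrame(self.positions, columns=["x_cm", "y_cm"]).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "DetectorLayout":
        df = pd.read_csv(Path(path))
        return cls(df[["x_cm", "y_cm"]].to_numpy())


def build_default_layout(central_half: float = 5.0, central_pitch: float = 1.0,
                         outer_half: float = 11.0, outer_pitch: float = 2.0,
                         transition_ring: bool = True) -> DetectorLayout:
    """Construct the 445-diode star layout from its verbal description.

    Central region: rows every ``central_pitch/2`` cm, diodes every
    ``central_pitch`` cm within a row, alternate rows shifted half a pitch —
    the checkerboard that gives the 0.707 cm diagonal spacing and 221 diodes
    over ±5 cm.  Outer region: the same pattern at double pitch over ±11 cm
    (204 diodes), plus a 20-diode transition ring at |5.5| cm completing the
    224-diode outer count.  The result is symmetric under 180° rotation.
    """
    pts: list[tuple[float, float]] = []

    def checkerboard(half: float, pitch: float, exclude_half: float | None) -> None:
        row = pitch / 2.0
        n = int(round(half / row))
        for iy in range(-n, n + 1):
            y = iy * row
            offset = 0.0 if iy % 2 == 0 else pitch / 2.0
            nx = int(np.floor((half - offset) / pitch + 1e-9))
            for ix in range(-nx - (1 if offset else 0), nx + 1):
                x = offset + ix * pitch
                if abs(x) > half + 1e-9:
                    continue
                if exclude_half is not None and abs(x) <= exclude_half + 1e-9 \
                        and abs(y) <= exclude_half + 1e-9:
                    continue
                pts.append((x, y))

    checkerboard(central_half, central_pitch, exclude_half=None)
    checkerboard(outer_half, outer_pitch, exclude_half=central_half)
    if transition_ring:
        ring = central_half + central_pitch / 2.0
        for t in (-4.0, -2.0, 0.0, 2.0, 4.0):
            pts.extend([(ring, t), (-ring, t), (t, ring), (t, -ring)])
    arr = np.array(sorted(set((round(x, 6), round(y, 6)) for x, y in pts)))
    return DetectorLayout(arr)


@dataclass(frozen=True)
class SampledPlane:
    """Sparse measurement on a working grid: NaN values where unsampled."""

    values: np.ndarray
    sampled: np.ndarray
    spacing: float
    origin: tuple[float, float]
    source_distance: float | None = None

    @property
    def n_missing(self) -> int:
        return int((~self.sampled).sum())

    def write_csv(self, path) -> None:
        """Sparse plane CSV: header as for dose planes, missing cells empty."""
        with open(path, "w") as fh:
            fh.write(f"# spacing_cm: {self.spacing!r}\n")
            fh.write(f"# origin_x_cm: {self.origin[0]!r}\n")
            fh.write(f"# origin_y_cm: {self.origin[1]!r}\n")
            sd = self.source_distance
            fh.write(f"# source_distance_cm: {'' if sd is None else repr(sd)}\n")
            for row in self.values:
                fh.write(",".join("" if not np.isfinite(v) else f"{v:.10g}" for v in row))
                fh.write("\n")


def sample_with_stepper(truth: DosePlane, layout: DetectorLayout,
                        step_cm: float = 0.2, n_steps: int = 1,
                        axis: str = "cross") -> SampledPlane:
    """Sample a truth plane at diode positions translated in 2 mm steps.

    The union of layout positions shifted by ``k·step_cm`` (k = 0..n_steps−1)
    along the cross-plane (x) axis is snapped to the truth grid; each snapped
    cell takes the bilinear sample of the truth there, every other cell is
    flagged missing.
    """
    if axis != "cross":
        raise InvalidInputError("only cross-plane stepper translation is supported")
    if n_steps < 1:
        raise InvalidInputError("n_steps must be >= 1")
    if step_cm <= 0:
        raise InvalidInputError("step_cm must be positive")
    sp = truth.spacing
    ny, nx = truth.values.shape
    out = np.full((ny, nx), np.nan)
    mask = np.zeros((ny, nx), dtype=bool)
    for k in range(n_steps):
        xs = layout.positions[:, 0] + k * step_cm
        ys = layout.positions[:, 1]
        j = np.floor((xs - truth.origin[0]) / sp + 0.5).astype(int)
        i = np.floor((ys - truth.origin[1]) / sp + 0.5).astype(int)
        if np.any(j < 0) or np.any(j >= nx) or np.any(i < 0) or np.any(i >= ny):
            raise CoverageError(
                "truth plane does not cover the stepped detector footprint"
            )
        vals = truth.sample(truth.origin[0] + j * sp, truth.origin[1] + i * sp)
        out[i, j] = vals
        mask[i, j] = True
    return SampledPlane(out, mask, sp, truth.origin, truth.source_distance)


def fill_missing(sampled: SampledPlane, filler: DosePlane) -> tuple[DosePlane, int]:
    """Fill unsampled cells from a film plane measured in the same setup.

    Measured cells are untouched.  Returns the completed plane and the number
    of cells that were filled.
    """
    ny, nx = sampled.values.shape
    if filler.values.shape != (ny, nx) \
            or abs(filler.spacing - sampled.spacing) > 1e-9 \
            or abs(filler.origin[0] - sampled.origin[0]) > 1e-9 \
            or abs(filler.origin[1] - sampled.origin[1]) > 1e-9:
        raise IncompleteFillerError("filler grid does not match the sampled grid")
    missing = ~sampled.sampled
    if np.any(~np.isfinite(filler.values[missing])):
        raise IncompleteFillerError("filler is missing values at unsampled cells")
    out = np.where(missing, filler.values, sampled.values)
    return (
        DosePlane(out, sampled.spacing, sampled.origin, sampled.source_distance),
        int(missing.sum()),
    )
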