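"""Slab phantoms and radiological path tracing along the beam axis.

The phantom is a stack of water-equivalent layers, each with a thickness and
an effective linear attenuation coefficient μ (cm⁻¹), whose proximal surface
sits at ``ssd`` cm from the source.  Ray tracing is parallel to the central
axis (gantry 0°, slab geometry): over a 22 cm field at 160 cm SDD the
divergent path through a slab differs from the axial one by < 1%, so the
axial path is used for every pixel.  Air between the exit surface and the
detector is treated as non-attenuating.

The attenuation correction factor restores the primary dose from the
detector back up to the reconstruction plane:

    ACF = exp(+Σᵢ μᵢ · ℓᵢ)

with ℓᵢ the in-phantom portion of the detector→plane path inside layer i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, OutOfRangeError
from .geometry import BeamGeometry

__all__ = ["SlabPhantom", "radiological_path", "acf"]


@dataclass(frozen=True)
class SlabPhantom:
    """Stack of (thickness_cm, mu_per_cm) layers, proximal surface at ``ssd``."""

    layers: tuple[tuple[float, float], ...]
    ssd: float

    def __post_init__(self) -> None:
        layers = tuple((float(t), float(mu)) for t, mu in self.layers)
        for t, mu in layers:
            if t < 0:
                raise InvalidInputError(f"layer thickness must be >= 0, got {t}")
            if mu < 0:
                raise InvalidInputError(f"mu must be >= 0, got {mu}")
        if not self.ssd > 0:
            raise InvalidInputError(f"ssd must be positive, got {self.ssd}")
        object.__setattr__(self, "layers", layers)

    @classmethod
    def homogeneous(cls, thickness: float, mu_eff: float, ssd: float) -> "SlabPhantom":
        return cls(((thickness, mu_eff),), ssd)

    @property
    def thickness(self) -> float:
        return sum(t for t, _ in self.layers)

    @property
    def mu_eff(self) -> float:
        """Thickness-weighted mean attenuation coefficient, cm⁻¹."""
        t = self.thickness
        if t == 0:
            return 0.0
        return sum(tt * mu for tt, mu in self.layers) / t

    def attenuation_between(self, z0: float, z1: float) -> float:
        """∫μ dz between depths z0 < z1 measured from the proximal surface."""
        if z1 < z0:
            z0, z1 = z1, z0
        total = 0.0
        top = 0.0
        for t, mu in self.layers:
            lo, hi = top, top + t
            seg = max(0.0, min(hi, z1) - max(lo, z0))
            total += mu * seg
            top = hi
        return total


def radiological_path(phantom: SlabPhantom, geometry: BeamGeometry,
                      depth: float) -> tuple[float, float]:
    """Physical distance and attenuation exponent from detector to a plane.

    The reconstruction plane sits at ``ssd + depth`` from the source.  Returns
    ``(physical_distance, attenuation_exponent)`` where the distance is the
    CAX path length from the detector to the plane and the exponent is
    Σ μᵢ·ℓᵢ over the in-phantom portion of that path (the air gap contributes
    zero).
    """
    t = phantom.thickness
    if not (-1e-12 <= depth <= t + 1e-12):
        raise OutOfRangeError(f"depth {depth} outside phantom [0, {t}]")
    depth = min(max(depth, 0.0), t)
    plane_dist = phantom.ssd + depth
    physical = geometry.sdd - plane_dist
    if physical < -1e-9:
        raise OutOfRangeError(
            f"plane at {plane_dist} cm lies beyond the detector at {geometry.sdd} cm"
        )
    exponent = phantom.attenuation_between(depth, t)
    return max(physical, 0.0), exponent


def acf(attenuation_exponent: float) -> float:
    """Attenuation correction factor e^(+exponent)."""
    if attenuation_exponent < 0:
        raise InvalidInputError(f"attenuation exponent must be >= 0, got {attenuation_exponent}")
    return math.exp(attenuation_exponent)
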