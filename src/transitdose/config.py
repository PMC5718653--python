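"""Run configuration: YAML/JSON parsing into the domain objects.

A run config describes the beam geometry, the slab phantom (layers of
thickness + μ), the aperture, grid settings, gamma criteria, table paths
and the seed.  All defaults are echoed back by ``as_dict`` so a logged
config fully describes its run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidInputError
from .geometry import ApertureMask, BeamGeometry
from .phantom import SlabPhantom
from .synthetic import ForwardModelConfig, default_conformal_aperture

__all__ = ["GammaSettings", "RunConfig", "load_config"]


@dataclass(frozen=True)
class GammaSettings:
    dose_pct: float = 3.0
    dta_mm: float = 3.0
    norm: str = "cax"
    low_dose_pct: float = 10.0


@dataclass(frozen=True)
class RunConfig:
    geometry: BeamGeometry
    phantom: SlabPhantom
    aperture: ApertureMask
    grid_spacing: float = 0.2
    grid_half_width: float = 12.0
    penumbra_sigma: float = 0.3
    noise_sigma: float = 0.0
    reference_dose: float = 100.0
    gamma: GammaSettings = field(default_factory=GammaSettings)
    tables_dir: Path | None = None
    seed: int = 0

    def forward_config(self) -> ForwardModelConfig:
        return ForwardModelConfig(
            geometry=self.geometry,
            phantom=self.phantom,
            aperture=self.aperture,
            penumbra_sigma=self.penumbra_sigma,
            reference_dose=self.reference_dose,
            grid_spacing=self.grid_spacing,
            grid_half_width=self.grid_half_width,
            noise_sigma=self.noise_sigma,
            seed=self.seed,
        )

    def as_dict(self) -> dict:
        return {
            "geometry": {
                "sdd_cm": self.geometry.sdd,
                "spd_cm": self.geometry.spd,
                "ssd_cm": self.geometry.ssd,
                "field_size_cm": self.geometry.field_size,
                "mu": self.geometry.mu,
            },
            "phantom": {
                "ssd_cm": self.phantom.ssd,
                "layers": [{"thickness_cm": t, "mu_per_cm": mu}
                           for t, mu in self.phantom.layers],
            },
            "grid": {"spacing_cm": self.grid_spacing,
                     "half_width_cm": self.grid_half_width},
            "penumbra_sigma_cm": self.penumbra_sigma,
            "noise_sigma": self.noise_sigma,
            "reference_dose_cgy": self.reference_dose,
            "gamma": {"dose_pct": self.gamma.dose_pct, "dta_mm": self.gamma.dta_mm,
                      "norm": self.gamma.norm, "low_dose_pct": self.gamma.low_dose_pct},
            "tables_dir": None if self.tables_dir is None else str(self.tables_dir),
            "seed": self.seed,
        }


def _parse_aperture(node, grid_spacing: float) -> ApertureMask:
    if node is None:
        return default_conformal_aperture()
    if "square" in node:
        return ApertureMask.square(float(node["square"]),
                                   spacing=float(node.get("spacing_cm", 0.1)))
    if "rectangles" in node:
        return ApertureMask.from_rectangles(
            node["rectangles"], spacing=float(node.get("spacing_cm", 0.1))
        )
    raise InvalidInputError("aperture must define 'square' or 'rectangles'")


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) run config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InvalidInputError(f"{path}: config must be a mapping")

    geo = data.get("geometry", {})
    geometry = BeamGeometry(
        sdd=float(geo.get("sdd_cm", 160.0)),
        spd=float(geo.get("spd_cm", 100.0)),
        ssd=float(geo.get("ssd_cm", 90.0)),
        field_size=tuple(geo["field_size_cm"]) if geo.get("field_size_cm") else None,
        mu=float(geo.get("mu", 0.0)),
    )
    ph = data.get("phantom", {})
    layers = ph.get("layers")
    if layers:
        phantom = SlabPhantom(
            tuple((float(l["thickness_cm"]), float(l["mu_per_cm"])) for l in layers),
            ssd=float(ph.get("ssd_cm", geometry.ssd)),
        )
    else:
        phantom = SlabPhantom.homogeneous(
            float(ph.get("thickness_cm", 20.0)),
            float(ph.get("mu_per_cm", 0.05)),
            float(ph.get("ssd_cm", geometry.ssd)),
        )
    grid = data.get("grid", {})
    gamma = data.get("gamma", {})
    tables_dir = data.get("tables_dir")
    return RunConfig(
        geometry=geometry,
        phantom=phantom,
        aperture=_parse_aperture(data.get("aperture"), float(grid.get("spacing_cm", 0.2))),
        grid_spacing=float(grid.get("spacing_cm", 0.2)),
        grid_half_width=float(grid.get("half_width_cm", 12.0)),
        penumbra_sigma=float(data.get("penumbra_sigma_cm", 0.3)),
        noise_sigma=float(data.get("noise_sigma", 0.0)),
        reference_dose=float(data.get("reference_dose_cgy", 100.0)),
        gamma=GammaSettings(
            dose_pct=float(gamma.get("dose_pct", 3.0)),
            dta_mm=float(gamma.get("dta_mm", 3.0)),
            norm=str(gamma.get("norm", "cax")),
            low_dose_pct=float(gamma.get("low_dose_pct", 10.0)),
        ),
        tables_dir=Path(tables_dir) if tables_dir else None,
        seed=int(data.get("seed", 0)),
    )
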