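"""Shared fixtures: forward-model configurations and calibrated tables.

Table building runs a dozen kernel fits, so the two closed-loop bundles
(conformal field and 5×5 cm² field) are session-scoped and shared between
the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import transitdose as td

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def conformal_config() -> td.ForwardModelConfig:
    """Irregular conformal segment through 20 cm of solid water at 160 cm SDD."""
    return td.ForwardModelConfig(aperture=td.default_conformal_aperture())


@pytest.fixture(scope="session")
def conformal_tables(conformal_config) -> td.ScatterTables:
    suite = td.make_calibration_suite(conformal_config)
    return td.build_tables(suite)


@pytest.fixture(scope="session")
def square5_config() -> td.ForwardModelConfig:
    """5×5 cm² field through the same slab, used for the depth-dose loop."""
    return td.ForwardModelConfig(aperture=td.ApertureMask.square(5.0))


@pytest.fixture(scope="session")
def square5_tables(square5_config) -> td.ScatterTables:
    suite = td.make_calibration_suite(square5_config)
    return td.build_tables(suite)


@pytest.fixture()
def uniform_transit() -> td.DosePlane:
    """Uniform 10 cGy transit plane at 160 cm on the 2 mm grid."""
    plane = td.centered_plane(12.0, 0.2, source_distance=160.0)
    return plane.with_values(np.full(plane.shape, 10.0))
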