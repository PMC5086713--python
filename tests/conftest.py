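"""Shared fixtures: generated scenes at several sizes.

Everything is generated programmatically; no fixture files.  The reference
scene (400 clustered stations, 30 days over four seasons, noise 10 μg/m³
on the revised scale, master seed 7) is session-scoped because several
test modules measure different properties of the same study conditions.
"""

from __future__ import annotations

import datetime as dt

import pytest

from gwrpm25 import pipeline
from gwrpm25.synthetic_scene import SceneConfig, generate_scene

ACCEPTANCE_SEED = 7


@pytest.fixture(scope="session")
def reference_scene():
    """The full reference study scene (expensive; built once)."""
    return generate_scene(SceneConfig(), seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def reference_rows(reference_scene):
    """Complete-case model rows per day plus a matching run config."""
    config = pipeline.config_for_scene(reference_scene)
    rows_by_day, excluded = pipeline.scene_model_rows(reference_scene, config)
    return rows_by_day, excluded, config


@pytest.fixture(scope="session")
def noiseless_scene():
    """Constant-coefficient, fully noise-free single-day scene (exact closure)."""
    cfg = SceneConfig.noiseless()
    return generate_scene(cfg, seed=ACCEPTANCE_SEED, dates=[dt.date(2015, 4, 10)])


@pytest.fixture(scope="session")
def small_scene():
    """A cheap 2-day scene for structural tests."""
    cfg = SceneConfig(
        lon_min=100.0,
        lon_max=103.0,
        lat_min=33.0,
        lat_max=36.0,
        n_stations=90,
        n_clusters=3,
    )
    dates = [dt.date(2015, 4, 10), dt.date(2015, 4, 11)]
    return generate_scene(cfg, seed=11, dates=dates)


@pytest.fixture(scope="session")
def small_rows(small_scene):
    config = pipeline.config_for_scene(small_scene)
    rows_by_day, _ = pipeline.scene_model_rows(small_scene, config)
    return rows_by_day, config
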