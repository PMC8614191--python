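"""Shared fixtures: small synthetic studies generated at test time."""

import logging

import numpy as np
import pytest

from streamtherm.config import HeatWave, PipelineConfig, SimConfig

logging.getLogger("streamtherm").setLevel(logging.ERROR)


def small_sim_config(**overrides) -> SimConfig:
    """A fast study: few sites, short record, two summer waves."""
    cfg = SimConfig(
        n_sites=4,
        n_years=2,
        start_year=2015,
        heat_waves=[HeatWave("2015-07-17"), HeatWave("2016-08-27")],
        catchment_km2_range=(1.5, 4.0),
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_study():
    """One shared 4-site study for read-only tests."""
    from streamtherm.synthetic import make_dataset

    return make_dataset(small_sim_config(), seed=42)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default study (92 sites, 7 years, 17 summer
    waves).  Session-scoped: run once, shared by the counting and
    sign-recovery checks."""
    from streamtherm.pipeline import run_pipeline

    cfg = PipelineConfig(seed=20120819)
    return run_pipeline(cfg)


@pytest.fixture
def small_pipeline_config(tmp_path):
    cfg = PipelineConfig(out_dir=tmp_path / "out")
    cfg.sim = small_sim_config()
    return cfg
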