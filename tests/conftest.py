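import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from uvrfret import FretParams, PopulationState, SimulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def params() -> FretParams:
    return FretParams()


@pytest.fixture
def wt_state() -> PopulationState:
    return PopulationState(construct="NcCg", genotype="WT", uv=False)


@pytest.fixture
def make_config():
    """Factory for small, fast simulation configs (96 px, 3 cells)."""

    def _make(**overrides) -> SimulationConfig:
        base = dict(
            state=PopulationState(construct="NcCg", genotype="WT", uv=False),
            n_cells=3,
            image_size=(96, 96),
            expression_level=200.0,
            seed=1234,
        )
        base.update(overrides)
        return SimulationConfig(**base)

    return _make


@pytest.fixture
def noiseless_config(make_config):
    def _make(**overrides) -> SimulationConfig:
        cfg = make_config(**overrides)
        return dataclasses.replace(
            cfg, shot_noise=False, noise_read_sd=0.0, scan_gain_cv=0.0
        )

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
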