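"""Shared fixtures: a fitted resampling transform, grids and a small
model instance, built once per session (the fit and the model are the
expensive pieces)."""

import numpy as np
import pytest
from hypothesis import settings

from scsaliency.mapping import build_sc_grid, fit_resampling_params
from scsaliency.model import ModelConfig, SCSaliencyModel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def resampling():
    return fit_resampling_params(n_restarts=30, seed=1)


@pytest.fixture(scope="session")
def grid200(resampling):
    return build_sc_grid(resampling, size=200)


@pytest.fixture(scope="session")
def mini_model(resampling):
    """Small working resolution / grid for end-to-end runs."""
    cfg = ModelConfig(px_per_deg=1.0, grid_size=64)
    return SCSaliencyModel(cfg, resampling=resampling)


@pytest.fixture(scope="session")
def default_model(resampling):
    """Full-size grid at the default working resolution."""
    return SCSaliencyModel(ModelConfig(), resampling=resampling)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
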