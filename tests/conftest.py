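import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import devochron as dc
from devochron.io import frame_to_profiles

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def quant_config():
    return dc.QuantConfig(spike_copies=2.6e8)


@pytest.fixture
def grid():
    return np.arange(0.0, 30.5, 1.0)


def make_profile(a, b, c, t0, grid, gene="g", rep="R1", sigma=0.0, rng=None):
    y = dc.log_sigmoid(grid, a, b, c, t0)
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=len(grid))
    return dc.ExpressionProfile(gene, rep, grid, 10.0 ** y)


@pytest.fixture
def make_sigmoid_profile(grid):
    def _make(a=4.0, b=3.0, c=1.0, t0=10.0, sigma=0.0, seed=0, gene="g", rep="R1"):
        return make_profile(a, b, c, t0, grid, gene, rep, sigma, np.random.default_rng(seed))
    return _make


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded study-condition dataset shared across tests."""
    cfg = dc.SimConfig(seed=7)
    df_a, df_b, truth = dc.generate_dataset(cfg)
    return cfg, df_a, df_b, truth


@pytest.fixture(scope="session")
def default_profiles(default_dataset):
    _, df_a, df_b, _ = default_dataset
    return frame_to_profiles(df_a, "A"), frame_to_profiles(df_b, "B")
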