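import numpy as np
import pytest

from groupfdr._types import ModelParams
from groupfdr.synthetic_data import SimConfig, simulate_full, simulate_z_ar1


@pytest.fixture(scope="session")
def small_z_dataset():
    """2,000-gene direct-z dataset with a clearly estimable signal."""
    cfg = SimConfig(N=2000, m=10, pi0=0.2, sigma=4.0, rho=0.2, seed=123)
    d, truth = simulate_z_ar1(cfg)
    return cfg, d, truth


@pytest.fixture(scope="session")
def small_full_dataset():
    """300-gene genotype-conditioned dataset (n=83 samples)."""
    cfg = SimConfig(N=300, m=5, n=83, pi0=0.2, sigma=5.0, rho=0.3, seed=7)
    d, truth = simulate_full(cfg)
    return cfg, d, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def mid_params():
    return ModelParams(pi0=0.5, sigma=1.0)
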