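import numpy as np
import pytest
from hypothesis import settings

from hoptrack import SimConfig, simulate

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One simulation trial at the reference parameter set."""
    return simulate(SimConfig(), seed=11)


@pytest.fixture(scope="session")
def no_hop_no_bleach_sim():
    """Hopping-free, bleach-free trial (pure association/diffusion/dissociation)."""
    cfg = SimConfig(p_reb=0.0, k_bleach=0.0)
    return simulate(cfg, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
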