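import numpy as np
import pytest

from ramcal import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """The full study-shaped campaign (83 samples x 2 scans, 3473 channels)."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def coarse_sim():
    """A coarse-axis campaign (spacing 4 cm^-1) for cheaper module tests."""
    cfg = SimulationConfig(seed=3, axis=(50.0, 3398.0, 4.0))
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
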