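import numpy as np
import pytest

from atg8kit.simulate import SimulationConfig, add_noise, simulate_field


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(n_cells=20, nf_true=0.35, coloc_true=0.60, seed=7)


@pytest.fixture(scope="session")
def noiseless_field(default_config):
    """One rendered field plus ground truth, shared across tests."""
    return simulate_field(default_config)


@pytest.fixture(scope="session")
def noisy_field(default_config, noiseless_field):
    field, records = noiseless_field
    return add_noise(field, default_config), records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def pairwise_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    return float((a & b).sum() / (a | b).sum())
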