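import numpy as np
import pytest

from wrenchnorm import CountMatrix, GroupDesign
from wrenchnorm.simulate import SimulationConfig, simulate_experiment


@pytest.fixture
def two_sample_counts():
    """The tiny worked example: samples [1,1,0] and [0,0,2]."""
    return CountMatrix(np.array([[1, 0], [1, 0], [0, 2]]), sample_ids=["a", "b"])


@pytest.fixture
def identical_counts():
    """Four identical samples (degenerate-prior conditions)."""
    col = np.array([5, 3, 2, 7, 1])
    return CountMatrix(np.tile(col[:, None], (1, 4)))


@pytest.fixture
def dense_rng_counts():
    """Random dense (all-positive) matrices for oracle-equivalence checks."""

    def make(seed, p=10, n=4, low=1, high=60):
        rng = np.random.default_rng(seed)
        return CountMatrix(rng.integers(low, high, size=(p, n)))

    return make


@pytest.fixture
def single_group_design():
    def make(counts):
        return GroupDesign.from_labels(counts.sample_ids, ["g"] * counts.n_samples)

    return make


@pytest.fixture(scope="session")
def sparse_sim():
    """One moderately sized 16S-like simulated dataset, shared across tests."""
    return simulate_experiment(
        SimulationConfig(p=1000, groups=(10, 10), f=0.1, depth_mean=10000, seed=11)
    )
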