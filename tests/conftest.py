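import numpy as np
import pytest

import thriftyshm as ts


@pytest.fixture(scope="session")
def truth3():
    """Small 3-mer ground truth (no hotspots: they need wider windows)."""
    return ts.random_ground_truth(3, seed=101, hotspots=())


@pytest.fixture(scope="session")
def truth5():
    """5-mer ground truth with the default AID hotspots."""
    return ts.random_ground_truth(5, seed=102)


@pytest.fixture(scope="session")
def small_dataset(truth5):
    return ts.simulate_dataset(truth5, n_pairs=60, length=150, seed=103)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
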