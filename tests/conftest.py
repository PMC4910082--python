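import numpy as np
import pytest

from histotex import extract_matrix, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """25 tiles/class at 150 px — the standard small fixture set."""
    return generate_dataset(n_per_class=25, size=150, seed=7)


@pytest.fixture(scope="session")
def small_best5(small_dataset):
    """best5 feature matrix of the small fixture set."""
    return extract_matrix(small_dataset, "best5")


@pytest.fixture
def separable_clusters():
    """Two well-separated Gaussian clusters (sigma 0.1, centres 10 apart)."""
    rng = np.random.default_rng(0)
    n = 50
    X = np.vstack([
        rng.normal(0.0, 0.1, size=(n, 4)),
        rng.normal(10.0, 0.1, size=(n, 4)),
    ])
    y = np.repeat([1, 2], n)
    return X, y
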