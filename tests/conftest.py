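import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_labeled_instance(rng, n_per_class=6, d=4, c=3, spread=2.0):
    """Small labelled Gaussian point cloud for scatter/discriminant tests."""
    centers = rng.normal(0.0, spread, size=(c, d))
    X = np.vstack([centers[j] + rng.normal(0.0, 1.0, size=(n_per_class, d))
                   for j in range(c)])
    y = np.repeat(np.arange(c), n_per_class)
    return X, y
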