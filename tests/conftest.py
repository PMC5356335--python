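import numpy as np
import pytest

from collabboost import LabeledDataset, SynthSpec, gaussian_blobs


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_blobs():
    """Well-separated 2-D blobs, 60 instances — trains fast, low noise."""
    return gaussian_blobs(SynthSpec(n=60, d=2, overlap=4.0, seed=3))


@pytest.fixture
def overlap_blobs():
    """Blobs with ~10% Bayes error, 200 instances."""
    return gaussian_blobs(SynthSpec(n=200, d=3, overlap=2.56, seed=7))


def random_dataset(rng, n=None, d=None):
    """A random labelled dataset with both classes present."""
    n = n or int(rng.integers(6, 31))
    d = d or int(rng.integers(1, 5))
    X = rng.normal(size=(n, d))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    y[0], y[1] = 1.0, -1.0  # guarantee both classes
    return LabeledDataset(X, y)


def random_weights(rng, n):
    w = rng.random(n) + 1e-3
    return w / w.sum()
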