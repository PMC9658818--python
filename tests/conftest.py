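import numpy as np
import pytest

import gaitfuse as gf


@pytest.fixture(scope="session")
def small_dataset():
    """A compact seeded dataset: 12 trials per class, default generator."""
    cfg = gf.SynthConfig(n_per_class=12, seed=11)
    trials = gf.generate_dataset(cfg)
    return cfg, trials


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Extracted 462-feature matrix of the compact dataset."""
    _, trials = small_dataset
    X, y = gf.extract_matrix(trials)
    return X, y


@pytest.fixture(scope="session")
def blob_data():
    """Well-separated 8-class Gaussian blobs: wide margin, 12 features."""
    rng = np.random.default_rng(42)
    means = rng.normal(0, 1, size=(8, 12)) * 10.0
    X, y = [], []
    for c in range(8):
        X.append(means[c] + rng.normal(0, 0.3, size=(15, 12)))
        y.append(np.full(15, c + 1))
    return np.vstack(X), np.concatenate(y)


def random_score_matrix(rng, n=3, m=8):
    """A random ScoreMatrix: rows drawn uniformly from the simplex."""
    z = rng.dirichlet(np.ones(m), size=n)
    return gf.ScoreMatrix(
        z=z, classifier_ids=tuple(range(1, n + 1)), class_ids=tuple(range(1, m + 1))
    )
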