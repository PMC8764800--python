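import numpy as np
import pytest

import brainnetga as bg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small separable two-class dataset shared across tests."""
    cfg = bg.SimConfig(n_nodes=12, n_per_class=20, n_planted=4,
                       effect_delta=0.5, subject_noise_sd=0.08, seed=42)
    data, edges = bg.generate_dataset(cfg)
    return data, edges


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    """A small classifier fitted once on the tiny dataset."""
    data, edges = tiny_dataset
    X, y = data.to_arrays()
    clf = bg.BrainNetGAClassifier(n_stages=1, conv_channels=4, e2e_channels=2,
                                  n2g_hidden=3, epochs=30, learning_rate=3e-3,
                                  batch_size=20, random_state=7)
    clf.fit(X, y)
    return clf, X, y, edges
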