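import numpy as np
import pytest

from wgdipc import SimConfig, encode_dataset, generate, planted_truth


@pytest.fixture(scope="session")
def small_planted():
    """A small binary planted dataset: (matrix, sorted planted indices)."""
    cfg = SimConfig(n_per_class=(40, 30), length_range=(50, 80), seed=2)
    records, labels = generate(cfg)
    matrix = encode_dataset(records, labels)
    planted = sorted({i for cls in planted_truth(cfg) for i in cls})
    return matrix, planted


@pytest.fixture(scope="session")
def random_problem():
    """A signal-free random selection problem (60 samples x 30 features)."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(60, 30))
    y = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
    return X, y
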