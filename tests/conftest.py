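import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """50×10 random table with a binary target tied to column 0."""
    X = rng.normal(size=(50, 10))
    y = (X[:, 0] + 0.3 * rng.normal(size=50) > 0).astype(int)
    return X, y
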