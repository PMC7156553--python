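import numpy as np
import pytest

from hicres.io import ContactMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_symmetric(n: int, rng, high: int = 50, resolution: int = 10_000) -> ContactMatrix:
    """Random symmetric non-negative integer contact matrix."""
    m = rng.integers(0, high, size=(n, n))
    m = np.triu(m) + np.triu(m, 1).T
    return ContactMatrix(m.astype(np.int64), resolution=resolution)


@pytest.fixture()
def symmetric_matrix(rng):
    return random_symmetric(60, rng)
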