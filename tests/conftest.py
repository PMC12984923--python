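import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_signal(seed: int, n: int = 30, lo: float = 0.0, hi: float = 255.0) -> np.ndarray:
    return np.random.default_rng(seed).uniform(lo, hi, size=n)


@pytest.fixture(scope="session")
def toy_table():
    """Small 2-class table: features 0 and 1 informative, the rest noise."""
    rng = np.random.default_rng(7)
    n = 60
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(0, 1, size=(n, 8))
    x[y == 1, 0] += 3.0
    x[y == 1, 1] -= 3.0
    return x, y
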