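import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_rgb(rng):
    """A small random RGB image in [0, 1]."""
    return rng.random((48, 48, 3))


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function over an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g
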