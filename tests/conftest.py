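import numpy as np
import pytest

from x3dfast import nn
from x3dfast.nn import Tensor


@pytest.fixture(autouse=True)
def _fixed_init_seed():
    """Deterministic parameter init / dropout for every test."""
    nn.set_seed(0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def feature(rng):
    """A small (N,T,C,H,W) feature volume."""
    return Tensor(rng.normal(size=(2, 4, 8, 6, 6)).astype(np.float32))


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function of the array ``x``."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        f_hi = f()
        x[i] = orig - eps
        f_lo = f()
        x[i] = orig
        g[i] = (f_hi - f_lo) / (2 * eps)
    return g
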