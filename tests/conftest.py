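import numpy as np
import pytest
from hypothesis import settings

from imcyolo import nn
from imcyolo.nn import Tensor

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _seeded_init():
    """Deterministic layer initialization for every test."""
    nn.seed_all(7)
    yield


@pytest.fixture
def feature_map(rng):
    def make(n=1, c=8, h=6, w=6, requires_grad=False):
        return Tensor(rng.standard_normal((n, c, h, w)).astype(np.float32),
                      requires_grad=requires_grad)

    return make


def zero_weights(module: nn.Module) -> nn.Module:
    """Zero every parameter (convenience for residual-identity checks)."""
    for p in module.parameters():
        p.data[:] = 0.0
    for name, b in module.named_buffers():
        if name.endswith("running_var"):
            b.data[:] = 1.0
        elif name.endswith("running_mean"):
            b.data[:] = 0.0
    return module


def finite_diff_grad(fn, x: np.ndarray, eps=1e-3):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        hi = fn(x)
        flat[i] = old - eps
        lo = fn(x)
        flat[i] = old
        gf[i] = (hi - lo) / (2 * eps)
    return g
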