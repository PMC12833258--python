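import numpy as np
import pytest

from hfseg import PhantomSpec, generate_phantom, tiny_model_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    return tiny_model_config()


@pytest.fixture(scope="session")
def tiny_phantoms():
    spec = PhantomSpec(size=64)
    return [generate_phantom(spec, 100 + i) for i in range(8)]


def numeric_grad(fn, x, eps=1e-6):
    """Central finite differences of a scalar-valued fn at ndarray x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = fn(x)
        x[idx] = orig - eps
        lo = fn(x)
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return g
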