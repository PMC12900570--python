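import numpy as np
import pytest

from gfssnet.phantom_io import PhantomConfig, generate_phantom, to_three_class


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """Clean (noise/bias free) small phantom shared across tests."""
    cfg = PhantomConfig(shape=(16, 48, 32), noise_sigma=0.0,
                        bias_strength=0.0, seed=7)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def small_phantom_three(small_phantom):
    pair, mask = small_phantom
    return pair, to_three_class(mask)


def numerical_gradient(f, x, eps=1e-4):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
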