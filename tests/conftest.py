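import numpy as np
import pytest

from lvscape import LVSystem, generate_sc


def random_cooperative_system(seed: int, n_lo: int = 2, n_hi: int = 5) -> LVSystem:
    """A random valid cooperative system with alphas straddling zero."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    sc = generate_sc(n, density=0.8, seed=int(rng.integers(2**31)), g=0.27)
    alpha = rng.normal(0.2, 0.5, size=n)
    return LVSystem(alpha=alpha, gamma=sc, g=0.27)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def decoupled7():
    return LVSystem(alpha=np.full(7, 0.5), gamma=np.zeros((7, 7)), g=0.27)


@pytest.fixture
def sc7():
    return generate_sc(7, density=0.5, seed=101, g=0.27)
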