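import numpy as np
import pytest

from specfuse.simulate import ps_fixture


@pytest.fixture(scope="session")
def ps_sequential():
    """Noise-free polystyrene validation pair (raman, libs)."""
    return ps_fixture("sequential")


@pytest.fixture(scope="session")
def ps_simultaneous():
    return ps_fixture("simultaneous")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_multinomial_problem(seed=0, n=120, p=20, K=3, informative=5, scale=2.0):
    """Seeded random multinomial instance with a planted sparse signal."""
    gen = np.random.default_rng(seed)
    informative = min(informative, p)
    X = gen.normal(size=(n, p))
    beta = np.zeros((p, K))
    beta[:informative] = gen.normal(scale=scale, size=(informative, K))
    eta = X @ beta
    probs = np.exp(eta - eta.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    y = np.array([gen.choice(K, p=row) for row in probs])
    return X, y
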