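import numpy as np
import pytest

from odit import OditParams, fit_nominal


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gaussian_model():
    """Exact-backend model on 2000 x 5 standard-Gaussian training rows."""
    gen = np.random.default_rng(7)
    X = gen.standard_normal((2000, 5))
    params = OditParams(k=1, s=1, gamma=1.0, alpha=0.05, n1_fraction=0.3, seed=3)
    return fit_nominal(X, params), X


@pytest.fixture(scope="session")
def squared_model():
    """Model with gamma=2 and k=s=2 (fully additive total distance)."""
    gen = np.random.default_rng(11)
    X = gen.standard_normal((1500, 4))
    params = OditParams(k=2, s=2, gamma=2.0, alpha=0.05, n1_fraction=0.3, seed=5)
    return fit_nominal(X, params)
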