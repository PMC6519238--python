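import numpy as np
import pytest

from carscreen.sample import SurvivalSample


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def censored_sample(rng):
    """Mid-sized lognormal AFT sample with ~25% censoring, d=6."""
    n, d = 400, 6
    X = rng.standard_normal((n, d))
    beta = np.array([0.8, -0.5, 0.3, 0.0, 0.0, 0.0])
    T = np.exp(X @ beta + rng.normal(0, 1.0, n))
    C = np.exp(rng.normal(1.2, 1.4, n))
    obs = np.minimum(T, C)
    status = (T <= C).astype(int)
    return SurvivalSample(obs, status, X), beta


@pytest.fixture
def uncensored_sample(rng):
    n, d = 200, 4
    X = rng.standard_normal((n, d))
    T = np.exp(X @ np.array([1.0, -0.5, 0.0, 0.0]) + rng.normal(0, 1, n))
    return SurvivalSample(T, np.ones(n, dtype=int), X)
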