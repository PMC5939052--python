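import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exgtools import ExGParams, exgauss_sample

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Table 2 (young_gng, maxLKHD columns) — the worked-example parameters
YOUNG_GNG = ExGParams(451.09, 47.33, 146.81)
# Table 2 (elder_gng, maxLKHD columns)
ELDER_GNG = ExGParams(524.49, 85.67, 306.65)
# canonical synthetic RT condition used throughout the simulations
TRUE = ExGParams(500.0, 50.0, 150.0)


@pytest.fixture(scope="session")
def young_gng():
    return YOUNG_GNG


@pytest.fixture(scope="session")
def elder_gng():
    return ELDER_GNG


@pytest.fixture(scope="session")
def true_params():
    return TRUE


@pytest.fixture(scope="session")
def sample_5000(true_params):
    return exgauss_sample(5000, true_params, seed=1)


@pytest.fixture(scope="session")
def sample_300(true_params):
    return exgauss_sample(300, true_params, seed=3)


@pytest.fixture(scope="session")
def high_skew_sample():
    """A sample whose empirical skewness exceeds 2 (moments inapplicable)."""
    x = exgauss_sample(400, ExGParams(500.0, 10.0, 300.0), seed=0)
    return x


def lamb_grid_params(lambs, M=500.0, S=150.0):
    """Params with mean M, SD S and the requested asymmetries."""
    out = []
    for lamb in lambs:
        tau = S * lamb
        sigma = S * np.sqrt(1.0 - lamb * lamb)
        out.append(ExGParams(M - tau, sigma, tau))
    return out
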