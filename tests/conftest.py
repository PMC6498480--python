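import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from recistvar import (
    ErrorDistribution,
    PosteriorDraws,
    default_variance_components,
    fit_bivariate_model,
    generate_readings,
    inter_error_cov,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def true_vc():
    return default_variance_components("long")


@pytest.fixture(scope="session")
def readings_small(true_vc):
    """30 lesions x 4 readers x 2 sessions, drawn from the known components."""
    return generate_readings(
        true_vc, n_lesions=30, n_readers=4, n_sessions=2,
        rng=np.random.default_rng(42),
    )


@pytest.fixture(scope="session")
def gibbs_posterior(readings_small):
    return fit_bivariate_model(
        readings_small, method="gibbs", n_chains=2, n_warmup=200, n_draws=200, seed=7
    )


@pytest.fixture(scope="session")
def degenerate_posterior(true_vc):
    """The true components wrapped as a single 'draw' (fixed error covariance)."""
    return PosteriorDraws(draws=[true_vc], n_chains=1)


@pytest.fixture(scope="session")
def inter_err(true_vc):
    return inter_error_cov(true_vc)


@pytest.fixture(scope="session")
def zero_err():
    return ErrorDistribution(mode="inter", cov=np.zeros((2, 2)))
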