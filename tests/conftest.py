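import numpy as np
import pytest

from geozinc import MaternParams
from geozinc.matern import build_covariance, cholesky_lower

SURVEY_SCALE = MaternParams(tau2=5.0, sigma2=3.3, phi=21.0, kappa=1.0)


def simulate_gaussian_response(locations, params, rng, mean=0.0):
    """Draw one response vector from the spatial LMM with the given truth."""
    n = len(locations)
    L = cholesky_lower(build_covariance(locations, params))
    return mean + L @ rng.standard_normal(n)


@pytest.fixture(scope="session")
def survey_params():
    """Random-effects truth at the survey's scale (nugget 5, sill 3.3, phi 21 km)."""
    return SURVEY_SCALE


@pytest.fixture(scope="session")
def small_survey(survey_params):
    """One seeded n=150 dataset with an easting trend, shared across tests."""
    rng = np.random.default_rng(2024)
    n = 150
    locs = np.c_[rng.uniform(0, 90, n), rng.uniform(0, 150, n)]
    X = np.c_[np.ones(n), locs[:, 0] - locs[:, 0].mean()]
    beta = np.array([10.0, 0.02])
    y = simulate_gaussian_response(locs, survey_params, rng, mean=X @ beta)
    return locs, X, y
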