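import numpy as np
import pytest
from hypothesis import settings

import assayrsm as ar
from assayrsm.datasets import FULL_TERMS, SELECTED_TERMS

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def experiment() -> ar.MeasurementSet:
    """The packaged 20-run optimization experiment."""
    return ar.datasets.load_optimization_experiment()


@pytest.fixture(scope="session")
def selected_fit(experiment) -> ar.RSMFit:
    return ar.fit_measurements(experiment, SELECTED_TERMS)


@pytest.fixture(scope="session")
def full_fit(experiment) -> ar.RSMFit:
    return ar.fit_measurements(experiment, FULL_TERMS)


@pytest.fixture
def three_factors() -> list[ar.FactorSpec]:
    return [
        ar.FactorSpec("phenol", 50.0, 25.0, allow_negative=True),
        ar.FactorSpec("h2so4", 250.0, 100.0, allow_negative=True),
        ar.FactorSpec("water", 50.0, 29.73, allow_negative=True),
    ]


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Independent brute-force OLS oracle: solve the normal equations."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    n, p = X.shape
    cov = rss / (n - p) * xtx_inv
    return beta, cov, rss
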