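import numpy as np
import pytest

from exposim import (
    CRFSet,
    ErrorParams,
    TruthModelParams,
    make_geography,
    make_monitor_network,
    simulate_truth,
)


@pytest.fixture(scope="session")
def small_geography():
    return make_geography(n_areas=50, extent_km=40.0, population_mean=1500.0, seed=11)


@pytest.fixture(scope="session")
def truth_params():
    return TruthModelParams(
        mu=30.0, sigma_S=5.0, phi_km=10.0, amp=5.0,
        rho_AR=0.5, sigma_C=4.0, sigma_E=3.0,
    )


@pytest.fixture(scope="session")
def small_field(small_geography, truth_params):
    return simulate_truth(small_geography, truth_params, n_days=120, seed=22)


@pytest.fixture(scope="session")
def crf():
    # high baseline rate keeps Monte-Carlo noise small at desk scale
    return CRFSet(beta0=np.log(2e-3), beta_ST=0.003, beta_LT=0.02, sigma_u=0.05)


@pytest.fixture(scope="session")
def identity_error():
    return ErrorParams()


@pytest.fixture(scope="session")
def tiny_network():
    return make_monitor_network(
        n_background=6, n_roadside=4, n_days=200, seed=3,
    )
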