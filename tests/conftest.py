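import numpy as np
import pytest

from ticscircuit import DEFAULT_PARAMS, SessionConfig, build_network, run_cohort


@pytest.fixture(scope="session")
def params():
    return dict(DEFAULT_PARAMS)


@pytest.fixture(scope="session")
def circuit(params):
    return build_network(params)


@pytest.fixture(scope="session")
def cohort10(params):
    """Ten simulated subjects under tic-condition inputs (shared across
    latency and protocol checks)."""
    return run_cohort(params, SessionConfig(), n_subjects=10, master_seed=2024)


@pytest.fixture(scope="session")
def cohort20(params):
    """Twenty simulated subjects under tic-condition inputs (shared by the
    peak-statistics and winner-take-all checks)."""
    return run_cohort(params, SessionConfig(), n_subjects=20, master_seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
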