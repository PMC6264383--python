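import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gradnf import (
    ScanProtocol,
    SubjectSimParams,
    build_localizer_run,
    build_nf_run,
    make_hrf,
)
from gradnf.pipeline import make_fixtures


@pytest.fixture(scope="session")
def protocol():
    return ScanProtocol()


@pytest.fixture(scope="session")
def nf_design(protocol):
    return build_nf_run(protocol, ("low", "high", "low", "high"))


@pytest.fixture(scope="session")
def loc_design(protocol):
    return build_localizer_run(protocol)


@pytest.fixture(scope="session")
def hrf(protocol):
    return make_hrf(tr=protocol.tr_seconds)


@pytest.fixture(scope="session")
def noiseless_params():
    """Deterministic generative parameters: no noise, no drift."""
    return SubjectSimParams(noise_sd=0.0, drift_slope=0.0, ar1_rho=0.0)


@pytest.fixture(scope="session")
def mini_cohort():
    """3-subject, 2-runs-per-region cohort shared across test modules."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
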