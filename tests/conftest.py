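import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stoptf import ExGaussParams, SSDSchedule, SubjectParams

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# generating values used throughout: a typical adult go-RT distribution
# (mean 500 ms) and a typical SSRT distribution (mean 240 ms)
GO = ExGaussParams(mu=440.0, sigma=80.0, tau=60.0)
STOP = ExGaussParams(mu=190.0, sigma=40.0, tau=50.0)

FIXED_LEVELS = [50.0, 150.0, 250.0, 350.0, 450.0]


@pytest.fixture(scope="session")
def go_params():
    return GO


@pytest.fixture(scope="session")
def stop_params():
    return STOP


@pytest.fixture(scope="session")
def subject_ptf10():
    return SubjectParams(go=GO, stop=STOP, ptf=0.1)


@pytest.fixture(scope="session")
def staircase():
    return SSDSchedule()


@pytest.fixture(scope="session")
def fixed_schedule():
    return SSDSchedule(mode="fixed", fixed_levels=FIXED_LEVELS)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
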