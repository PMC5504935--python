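import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from p300ifce import FuzzyParams, default_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def o1_params() -> FuzzyParams:
    """Published parameter row for object O1."""
    return FuzzyParams(alpha1=0.2, alpha2=0.3, rho_m=0.2, sigma=0.5)


@pytest.fixture(scope="session")
def dataset():
    return default_dataset()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
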