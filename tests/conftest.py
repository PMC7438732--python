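import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppase_kinetics import ComplexationConstants

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_constants() -> ComplexationConstants:
    return ComplexationConstants.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
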