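import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oadx import DecisionLimits, study_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture():
    """The validation study's printed counts."""
    return study_fixture()


@pytest.fixture()
def limits():
    """COMP gate 1500 ng/mL plus an illustrative ratio gate of 2.0
    (the validated ratio limit is unpublished)."""
    return DecisionLimits(comp_limit=1500.0, ratio_limit=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
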