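import pytest
from hypothesis import HealthCheck, settings

from acidflux.design import ExperimentDesign, GroundTruth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def design():
    return ExperimentDesign(seed=7)


@pytest.fixture
def small_design():
    return ExperimentDesign(replicates_per_condition=2, seed=7)


@pytest.fixture
def truth():
    return GroundTruth()
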