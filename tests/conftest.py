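import pytest
from hypothesis import HealthCheck, settings

from coolspike import POOLED_PARAMS, SigmoidParams, TemperatureRegime, study_regime

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def pooled_params() -> SigmoidParams:
    """The pooled-data induction curve (Ymax=99.31181, B=83.4511, K=594.1813)."""
    return POOLED_PARAMS


@pytest.fixture
def khm1220_regime() -> TemperatureRegime:
    """27/23 °C vegetative against the 22/19 °C cooling room: 110 °C·h/day."""
    return study_regime("KHM1220")


@pytest.fixture
def khm1431_regime() -> TemperatureRegime:
    """32/24 °C vegetative against the 22/19 °C cooling room: 190 °C·h/day."""
    return study_regime("KHM1431")
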