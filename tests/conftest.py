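import pytest
from hypothesis import HealthCheck, settings

from isletchip import (ChipConfig, ModelParameters, simulate_protocol,
                       standard_protocol)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def config():
    return ChipConfig()


@pytest.fixture(scope="session")
def hyper_run(params, config):
    """One adaptive 15-day hyperglycemic simulation shared across tests."""
    protocol = standard_protocol("hyper", gtt_days=(1, 13), config=config)
    return simulate_protocol(params, None, config, protocol)
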