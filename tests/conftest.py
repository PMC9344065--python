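import pytest
from hypothesis import HealthCheck, settings

from dnadroplet import EncodingConfig

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cfg() -> EncodingConfig:
    return EncodingConfig()
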