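import pytest
from hypothesis import HealthCheck, settings

from booltrap.fixtures import builtin_fixtures

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nets():
    return builtin_fixtures()
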