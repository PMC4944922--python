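import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from infoseek import TrialConfig, build_state_tree


@pytest.fixture(scope="session")
def trees():
    """State trees for every cost condition at the fixed 3 s/card rate."""
    return {c: build_state_tree(TrialConfig(cost_cents=c)) for c in (0, 1, 3, 5)}
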