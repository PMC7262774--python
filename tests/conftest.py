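import pytest
from hypothesis import HealthCheck, settings

from icrscan import synthetic_motif_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def motif_set():
    """The shipped synthetic composite set (NOT the published one)."""
    return synthetic_motif_set()
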