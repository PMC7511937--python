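import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def ramp_map():
    """3×4 map with values 10·r + c, handy for hand-indexed crops."""
    r = np.arange(3)[:, None]
    c = np.arange(4)[None, :]
    return (10 * r + c).astype(float)
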