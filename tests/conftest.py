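import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nmdanet.gating import GatingParams, compute_jump_constants

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gp():
    """Default NMDA kinetics (alpha=0.5/ms, tau_r=2 ms, tau_d=100 ms)."""
    return GatingParams()


@pytest.fixture(scope="session")
def jc(gp):
    return compute_jump_constants(gp)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
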