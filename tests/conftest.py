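import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ddcbind.models import BindingParams, DesignConstants, RetentionParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def consts():
    """Reference design constants: 30 ul beads / 0.5 ml, top titration 50 uM."""
    return DesignConstants(s_star=0.06, T_star=50e-6)


@pytest.fixture
def coop_params():
    """A moderately cooperative complete-DDC parameter set."""
    return BindingParams(K_nc=20e-6, kappa=12000.0, kappa_inf=12000.0, N=4.0)


@pytest.fixture
def ret_params():
    return RetentionParams(b=0.02, r=0.8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
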