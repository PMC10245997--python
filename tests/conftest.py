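import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from reflexsim import HReflexParams
from reflexsim.environment import Condition, DialState, RunState


@pytest.fixture
def noiseless_params():
    """Deterministic model: no biological variability, no measurement noise."""
    return HReflexParams(sigma2=0.0, noise_aN=0.0)


@pytest.fixture
def default_params():
    return HReflexParams()


def make_run_state(condition=None, params=None, theta_tar=0.0, theta0=0.0, seed=0):
    condition = condition or Condition("C5", "Kr", "LV", "MT")
    params = params or HReflexParams(sigma2=0.0, noise_aN=0.0)
    return RunState(
        condition=condition,
        params=params,
        theta_tar=theta_tar,
        seed=seed,
        dial=DialState(theta=theta0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
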