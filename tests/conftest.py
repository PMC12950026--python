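import numpy as np
import pytest

from propriosnn.neurons import AdExParams, LIFParams
from propriosnn.network import default_config
from propriosnn.stimuli import JointAngleTrace, SyntheticGaitParams, synthetic_gait

DT = 0.25


@pytest.fixture(scope="session")
def adex_params():
    return AdExParams()


@pytest.fixture(scope="session")
def velocity_lif():
    """The published high-pass LIF parameterisation used in worked examples."""
    return LIFParams(tau=5.0, omega=10.8)


@pytest.fixture(scope="session")
def default_cfg():
    """Default extended-plate encoder over a 0-180 deg working range."""
    return default_config((0.0, 180.0), N_h=50, extended=True, dt=DT)


@pytest.fixture(scope="session")
def gait_trace():
    """A 3-second synthetic stepping trace on the simulation grid."""
    p = SyntheticGaitParams(duration=3000.0, dt=DT, seed=11, working_range=(20.0, 160.0))
    return synthetic_gait(p)


def constant_trace(theta: float, duration: float, dt: float = DT) -> JointAngleTrace:
    n = int(round(duration / dt))
    return JointAngleTrace(np.arange(n) * dt, np.full(n, float(theta)))


@pytest.fixture(scope="session")
def make_constant_trace():
    return constant_trace
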