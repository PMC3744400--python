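import numpy as np
import pytest

from delaylqg.control import CostSpec, lqr_gains
from delaylqg.dynamics import ModelParams, augment, discretize
from delaylqg.estimation import KalmanFilter, NoiseSpec


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def block(params):
    return discretize(params)


@pytest.fixture(scope="session")
def aug(block, params):
    return augment(block, params.delay_steps)


@pytest.fixture(scope="session")
def cost():
    return CostSpec()


@pytest.fixture(scope="session")
def law(aug, cost):
    return lqr_gains(aug, cost)


@pytest.fixture(scope="session")
def noise():
    return NoiseSpec()


@pytest.fixture(scope="session")
def kf(aug, noise):
    return KalmanFilter(aug, noise)


def make_trace(t, theta, theta_dot=None, t_e=None, x_hat=None, target=0.0,
               onset=0.0, abort_step=None):
    """Hand-built SimulationTrace for analysis-level tests."""
    from delaylqg.simulate import SimulationTrace

    t = np.asarray(t, dtype=float)
    n = t.size
    x = np.zeros((n, 5))
    x[:, 0] = theta
    if theta_dot is None:
        theta_dot = np.gradient(np.asarray(theta, float), t)
    x[:, 1] = theta_dot
    if t_e is not None:
        x[:, 3] = t_e
    x[:, 4] = target
    xh = x.copy() if x_hat is None else np.asarray(x_hat, float)
    dt = float(t[1] - t[0])
    return SimulationTrace(t=t, x=x, x_hat=xh, u=np.zeros(n),
                           y=np.zeros((n, 5)), condition="synthetic",
                           onset=onset, dt=dt, abort_step=abort_step)
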