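"""Single-joint plant dynamics, Euler discretization and delay augmentation.

The plant is a rigid body rotating about one axis (an elbow-like joint)
driven by a muscle-like torque actuator.  The joint obeys

    I * theta_ddot = T_C + T_E - G * theta_dot

where ``T_C`` is the controlled torque, produced by a first-order low-pass
response to the control variable ``u`` with time constant ``tau``:

    tau * T_C_dot = u - T_C

and ``T_E`` is an external (perturbation) torque, modelled internally as
constant (``T_E_dot = 0``).  The target angle ``theta*`` is carried as a
constant state entry so the tracking error ``theta - theta*`` is linear in
the state.

Sensory feedback reaches the controller with a delay of ``h`` discrete
steps.  Stacking the current state with the ``h`` previous states turns the
delayed-observation problem into a standard one: the observation matrix
simply reads out the oldest block of the augmented state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Number of entries in one (non-augmented) state block:
#: (theta, theta_dot, T_C, T_E, theta_star).
STATE_DIM = 5

#: Index of each state entry within a block.
IDX_THETA, IDX_THETA_DOT, IDX_TC, IDX_TE, IDX_TARGET = range(STATE_DIM)


@dataclass(frozen=True)
class ModelParams:
    """Physical and timing constants of the single-joint plant.

    Parameters
    ----------
    inertia : float
        Moment of inertia of the joint, kg m^2.
    viscosity : float
        Viscous coefficient, N m s / rad (torque per unit angular velocity).
    tau : float
        Time constant of the first-order muscle low-pass, s.
    dt : float
        Discretization time step, s.
    delay_steps : int
        Feedback delay expressed in number of time steps; the modelled
        delay is ``delay_steps * dt``.
    target_rad : float
        Prescribed joint angle theta*, rad.
    """

    inertia: float = 0.065
    viscosity: float = 0.05
    tau: float = 0.060
    dt: float = 0.010
    delay_steps: int = 6
    target_rad: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.inertia, self.viscosity, self.tau,
                            self.dt, self.target_rad]).all():
            raise ValueError("ModelParams entries must be finite")
        if self.inertia <= 0:
            raise ValueError(f"inertia must be > 0, got {self.inertia}")
        if self.viscosity < 0:
            raise ValueError(f"viscosity must be >= 0, got {self.viscosity}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if int(self.delay_steps) != self.delay_steps or self.delay_steps < 0:
            raise ValueError(
                f"delay_steps must be a nonnegative integer, got {self.delay_steps}")

    @property
    def delay_s(self) -> float:
        """Feedback delay in seconds (``delay_steps * dt``)."""
        return self.delay_steps * self.dt


def joint_state(theta: float = 0.0, theta_dot: float = 0.0, t_c: float = 0.0,
                t_e: float = 0.0, target: float = 0.0) -> np.ndarray:
    """Assemble a state vector (theta, theta_dot, T_C, T_E, theta*)."""
    x = np.array([theta, theta_dot, t_c, t_e, target], dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("joint state entries must be finite")
    return x


def derivative(state: np.ndarray, u: float, params: ModelParams) -> np.ndarray:
    """Continuous-time derivative of the joint state.

    Returns ``(theta_dot, (T_C + T_E - G*theta_dot)/I, (u - T_C)/tau, 0, 0)``.
    The external torque and the target are internally constant.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (STATE_DIM,):
        raise ValueError(f"state must have shape ({STATE_DIM},), got {state.shape}")
    if not (np.isfinite(state).all() and np.isfinite(u)):
        raise ValueError("derivative: non-finite state or control input")
    theta_dot = state[IDX_THETA_DOT]
    t_c = state[IDX_TC]
    t_e = state[IDX_TE]
    return np.array([
        theta_dot,
        (t_c + t_e - params.viscosity * theta_dot) / params.inertia,
        (u - t_c) / params.tau,
        0.0,
        0.0,
    ])


@dataclass(frozen=True)
class LinearSystem:
    """Discrete-time linear system ``x' = A x + B u`` over one state block."""

    A: np.ndarray
    B: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if self.A.shape != (STATE_DIM, STATE_DIM):
            raise ValueError(f"A must be {STATE_DIM}x{STATE_DIM}")
        if self.B.shape != (STATE_DIM, 1):
            raise ValueError(f"B must be {STATE_DIM}x1")


def discretize(params: ModelParams) -> LinearSystem:
    """Euler discretization of the joint dynamics with time step ``dt``.

    ``A = I + dt*J`` with ``J`` the Jacobian of :func:`derivative`; ``B`` is
    nonzero only in the controlled-torque row.  The external-torque and
    target rows of ``A`` are unit rows (internal constancy assumption: the
    estimator treats any perturbation as a step held constant over the
    delay interval).  An internal model with a constant nonzero torque
    drift is available as an affine option on the Kalman filter, where the
    drift term lives naturally.
    """
    dt = params.dt
    A = np.eye(STATE_DIM)
    A[IDX_THETA, IDX_THETA_DOT] = dt
    A[IDX_THETA_DOT, IDX_THETA_DOT] = 1.0 - dt * params.viscosity / params.inertia
    A[IDX_THETA_DOT, IDX_TC] = dt / params.inertia
    A[IDX_THETA_DOT, IDX_TE] = dt / params.inertia
    A[IDX_TC, IDX_TC] = 1.0 - dt / params.tau
    B = np.zeros((STATE_DIM, 1))
    B[IDX_TC, 0] = dt / params.tau
    return LinearSystem(A=A, B=B, dt=dt)


@dataclass(frozen=True)
class AugmentedLinearSystem:
    """Delay-augmented system over ``z = (x_t, x_{t-1}, ..., x_{t-h})``.

    The first block row of ``A_aug`` advances the newest state by the
    one-step dynamics; every other block row is a pure shift copying block
    ``k-1`` into block ``k``.  ``B_aug`` feeds the control into the newest
    block only.  ``H`` reads out the oldest block: the only part of the
    augmented state the controller can observe is the state ``h`` steps ago.
    """

    A: np.ndarray
    B: np.ndarray
    H: np.ndarray
    delay_steps: int
    block: LinearSystem = field(repr=False)

    @property
    def dim(self) -> int:
        return STATE_DIM * (self.delay_steps + 1)

    def newest(self, z: np.ndarray) -> np.ndarray:
        """Newest (current-time) block of an augmented vector."""
        return np.asarray(z)[:STATE_DIM]

    def oldest(self, z: np.ndarray) -> np.ndarray:
        """Oldest (observable) block of an augmented vector."""
        return np.asarray(z)[-STATE_DIM:]


def augment(system: LinearSystem, h: int) -> AugmentedLinearSystem:
    """Build the delay-augmented system for a feedback delay of ``h`` steps."""
    if int(h) != h or h < 0:
        raise ValueError(f"delay steps h must be a nonnegative integer, got {h}")
    h = int(h)
    n = STATE_DIM
    dim = n * (h + 1)
    A_aug = np.zeros((dim, dim))
    A_aug[:n, :n] = system.A
    for k in range(1, h + 1):
        A_aug[k * n:(k + 1) * n, (k - 1) * n:k * n] = np.eye(n)
    B_aug = np.zeros((dim, 1))
    B_aug[:n, :] = system.B
    H = np.zeros((n, dim))
    H[:, -n:] = np.eye(n)
    return AugmentedLinearSystem(A=A_aug, B=B_aug, H=H, delay_steps=h,
                                 block=system)
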