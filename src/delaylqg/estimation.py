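"""State estimation with and without delay compensation.

The delay-aware estimator is a Kalman filter on the delay-augmented system:
the observation is the state ``h`` steps in the past, and a single
innovation simultaneously corrects the whole stored history of joint
angles, velocities and torques over the delay interval.  The newest block
of the corrected estimate is therefore an extrapolation of the delayed
sensory data through the internal model — a sensory prediction.

The naive variant ignores the delay: it runs a standard Kalman filter on
the non-augmented model and treats the physically delayed measurement as
if it were current.  This violates the filter's conditional-distribution
assumption and renders the closed loop prone to instability.

All gains are computed at steady state (converged covariance recursion),
matching a stationary postural task.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import (
    STATE_DIM,
    AugmentedLinearSystem,
    LinearSystem,
)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise variances of the closed loop.

    All noises are zero-mean Gaussian.  ``sigma_motor`` is the variance of
    the motor noise added to the control signal; ``sigma_meas`` the variance
    of the measurement noise added to every entry of the observed state;
    ``sigma_pred`` the variance of the noise corrupting the prior estimate
    in the prediction step.  ``feedback_weight_scale`` multiplies the
    converged Kalman gain (1 = optimal weighting; 1/20 reproduces the
    reduced-sensory-weight variant).  ``pred_noise_full`` places the
    prediction noise on the full augmented diagonal instead of the newest
    block only.
    """

    sigma_motor: float = 1e-6
    sigma_meas: float = 1e-6
    sigma_pred: float = 1e-6
    feedback_weight_scale: float = 1.0
    pred_noise_full: bool = False

    def __post_init__(self) -> None:
        for name in ("sigma_motor", "sigma_meas", "sigma_pred"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be a finite nonnegative variance")
        if not (0 < self.feedback_weight_scale <= 1):
            raise ValueError("feedback_weight_scale must be in (0, 1]")


def process_noise_cov(system: AugmentedLinearSystem | LinearSystem,
                      noise: NoiseSpec) -> np.ndarray:
    """Process-noise covariance used by the filter.

    Motor noise enters through the control channel (``B sigma_motor B^T``);
    prediction noise is placed on the diagonal of the newest block (or the
    full diagonal when ``pred_noise_full``).
    """
    B = system.B
    Q = noise.sigma_motor * (B @ B.T)
    dim = B.shape[0]
    if noise.pred_noise_full:
        Q = Q + noise.sigma_pred * np.eye(dim)
    else:
        idx = np.arange(STATE_DIM)
        Q[idx, idx] += noise.sigma_pred
    return Q


def measurement_noise_cov(noise: NoiseSpec) -> np.ndarray:
    """Measurement-noise covariance: ``sigma_meas`` on all five entries."""
    return noise.sigma_meas * np.eye(STATE_DIM)


def _observation(system: AugmentedLinearSystem | LinearSystem) -> np.ndarray:
    if isinstance(system, AugmentedLinearSystem):
        return system.H
    return np.eye(STATE_DIM)


def compute_kalman_gains(system: AugmentedLinearSystem | LinearSystem,
                         noise: NoiseSpec,
                         tol: float = 1e-12,
                         max_iter: int = 100_000,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state Kalman gain and prior covariance.

    Iterates the prior-covariance recursion

        P <- A (P - P H^T (H P H^T + R)^-1 H P) A^T + Q

    to a fixed point (successive-iterate Frobenius norm below ``tol``) and
    returns ``(K, P)`` with ``K = P H^T (H P H^T + R)^-1``.  If the spec
    requests a reduced feedback weight, the converged gain is scaled by
    ``feedback_weight_scale``.

    Raises
    ------
    RuntimeError
        If the recursion has not converged after ``max_iter`` iterations;
        the message reports the last residual.
    """
    A = system.A
    H = _observation(system)
    Q = process_noise_cov(system, noise)
    R = measurement_noise_cov(noise)
    P = Q.copy()
    residual = np.inf
    for _ in range(max_iter):
        S = H @ P @ H.T + R
        K = np.linalg.solve(S.T, (P @ H.T).T).T
        P_next = A @ (P - K @ H @ P) @ A.T + Q
        P_next = 0.5 * (P_next + P_next.T)
        residual = np.linalg.norm(P_next - P)
        if residual < tol:
            P = P_next
            break
        P = P_next
    else:
        raise RuntimeError(
            f"Kalman covariance recursion did not converge in {max_iter} "
            f"iterations; last residual {residual:.3e}")
    S = H @ P @ H.T + R
    K = np.linalg.solve(S.T, (P @ H.T).T).T
    return noise.feedback_weight_scale * K, P


@dataclass
class EstimatorState:
    """Estimate, prior covariance and gain of a Kalman filter.

    ``z_hat`` is the current corrected estimate; ``P`` the *prior*
    covariance used for the next correction; ``K`` the gain applied at the
    last correction.  ``steady_state`` marks whether ``K`` is held fixed at
    its converged value (the default for postural simulations) or updated
    every step from the covariance recursion.
    """

    z_hat: np.ndarray
    P: np.ndarray
    K: np.ndarray | None = None
    steady_state: bool = True

    def copy(self) -> "EstimatorState":
        return EstimatorState(self.z_hat.copy(), self.P.copy(),
                              None if self.K is None else self.K.copy(),
                              self.steady_state)


class KalmanFilter:
    """Kalman filter over a (possibly delay-augmented) linear system.

    Parameters
    ----------
    system : AugmentedLinearSystem or LinearSystem
        The internal model.  An augmented system yields the delay-aware
        filter; a plain system yields the naive, delay-ignoring filter
        (its observation matrix is the identity, so whatever measurement
        is supplied is treated as the current state).
    noise : NoiseSpec
        Noise variances; also sets the feedback-weight scaling.
    steady_state : bool
        Use the converged gain for every step (default).  When False the
        gain and covariance are propagated exactly, which is what the
        batch-conditioning equivalence requires.
    te_slope : float
        Optional internal-model drift of the external torque (Nm/s) added
        to the prediction; 0 keeps the constant-torque prior.
    """

    def __init__(self, system: AugmentedLinearSystem | LinearSystem,
                 noise: NoiseSpec, steady_state: bool = True,
                 te_slope: float = 0.0) -> None:
        self.system = system
        self.noise = noise
        self.steady_state = steady_state
        self.te_slope = float(te_slope)
        self.H = _observation(system)
        self.Q = process_noise_cov(system, noise)
        self.R = measurement_noise_cov(noise)
        self.dim = system.A.shape[0]
        self.dt = system.block.dt if isinstance(system, AugmentedLinearSystem) \
            else system.dt
        if steady_state:
            self.K_ss, self.P_ss = compute_kalman_gains(system, noise)
        else:
            self.K_ss = self.P_ss = None

    def init_state(self, z0: np.ndarray | None = None,
                   P0: np.ndarray | None = None) -> EstimatorState:
        """Initial estimator state (prior mean and covariance at t=0)."""
        z0 = np.zeros(self.dim) if z0 is None else np.asarray(z0, float).copy()
        if z0.shape != (self.dim,):
            raise ValueError(f"z0 must have shape ({self.dim},)")
        if self.steady_state:
            P0 = self.P_ss.copy() if P0 is None else np.asarray(P0, float)
        else:
            P0 = self.Q.copy() if P0 is None else np.asarray(P0, float).copy()
        return EstimatorState(z_hat=z0, P=P0, K=self.K_ss,
                              steady_state=self.steady_state)

    def predict(self, est: EstimatorState, u: float,
                pred_noise: np.ndarray | None = None) -> EstimatorState:
        """Prior estimate from the internal model and the motor command.

        ``pred_noise`` is an optional realization of the prediction noise
        zeta corrupting the prior (used by the closed-loop simulation).
        """
        z_prior = self.system.A @ est.z_hat + self.system.B[:, 0] * u
        if self.te_slope:
            # affine drift of the internal external-torque model
            from .dynamics import IDX_TE
            z_prior[IDX_TE] += self.te_slope * self.dt
        if pred_noise is not None:
            z_prior = z_prior + pred_noise
        if est.steady_state:
            P = est.P
        else:
            P = self.system.A @ est.P @ self.system.A.T + self.Q
            P = 0.5 * (P + P.T)
        return EstimatorState(z_hat=z_prior, P=P, K=est.K,
                              steady_state=est.steady_state)

    def correct(self, est: EstimatorState, y: np.ndarray) -> EstimatorState:
        """Correct a prior estimate with the innovation, weighted by the gain."""
        y = np.asarray(y, dtype=float)
        if y.shape != (STATE_DIM,):
            raise ValueError(f"observation must have shape ({STATE_DIM},)")
        if est.steady_state:
            K = self.K_ss
            P = est.P
        else:
            S = self.H @ est.P @ self.H.T + self.R
            K = np.linalg.solve(S.T, (est.P @ self.H.T).T).T
            K = self.noise.feedback_weight_scale * K
            P = est.P - K @ self.H @ est.P
            P = 0.5 * (P + P.T)
        innovation = y - self.H @ est.z_hat
        z = est.z_hat + K @ innovation
        return EstimatorState(z_hat=z, P=P, K=K, steady_state=est.steady_state)

    def step(self, est: EstimatorState, u: float, y: np.ndarray,
             pred_noise: np.ndarray | None = None) -> EstimatorState:
        """One predict-correct cycle: prior from ``u``, correction by ``y``."""
        return self.correct(self.predict(est, u, pred_noise), y)


def kf_step(est: EstimatorState, u: float, y: np.ndarray,
            system: AugmentedLinearSystem, noise: NoiseSpec | None = None,
            ) -> EstimatorState:
    """Functional one-step interface to the delay-aware filter."""
    kf = KalmanFilter(system, noise or NoiseSpec(),
                      steady_state=est.steady_state)
    return kf.step(est, u, y)


def naive_kf_step(est: EstimatorState, u: float, y: np.ndarray,
                  system: LinearSystem, noise: NoiseSpec | None = None,
                  ) -> EstimatorState:
    """Functional one-step interface to the delay-ignoring filter.

    ``y`` is the physically delayed measurement; the filter treats it as
    current.  No delay compensation is performed.
    """
    if isinstance(system, AugmentedLinearSystem):
        raise TypeError("naive filter runs on the non-augmented LinearSystem")
    kf = KalmanFilter(system, noise or NoiseSpec(),
                      steady_state=est.steady_state)
    return kf.step(est, u, y)


def scale_feedback_weight(noise: NoiseSpec, factor: float) -> NoiseSpec:
    """NoiseSpec with the Kalman gain scaled by ``factor`` (e.g. 1/20)."""
    return replace(noise, feedback_weight_scale=factor)
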