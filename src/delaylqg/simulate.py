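"""Closed-loop trial engine: plant + estimator + controller + perturbations.

One trial advances the true (augmented) plant state step by step, feeds the
controller the delayed, noisy observation, updates the state estimate
according to the chosen condition, and applies the linear control law to
the estimate:

``delay_aware``
    Kalman filter on the delay-augmented system (full delay compensation).
``naive``
    Kalman filter on the non-augmented model that treats the physically
    delayed measurement as current; with the default parameters this loop
    is unstable under perturbations.
``reduced_gain``
    The naive filter with its Kalman gain scaled down by 1/20 — stable,
    but with sluggish corrections.
``perfect_state``
    The control signal is forced to zero for one feedback delay after
    perturbation onset, then the feedback gains act on the true state.
    This emulates an ideal estimator whose priors match the perturbation
    profile exactly (the blocked-condition benchmark).

External torques are defined in continuous time as piecewise-linear
profiles and sampled at the left edge of each time step (sample-and-hold);
on the 10 ms grid the experimental 5 ms build-up collapses to a single
step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .control import ControlLaw, CostSpec, lqr_gains, lqr_schedule
from .dynamics import (
    IDX_TARGET,
    IDX_TC,
    IDX_TE,
    IDX_THETA,
    IDX_THETA_DOT,
    STATE_DIM,
    AugmentedLinearSystem,
    LinearSystem,
    ModelParams,
    augment,
    discretize,
)
from .estimation import KalmanFilter, NoiseSpec, scale_feedback_weight

CONDITIONS = ("delay_aware", "naive", "reduced_gain", "perfect_state")

#: Joint angle (rad) beyond which a diverging trial is aborted.
ABORT_ANGLE_RAD = 1e6

#: Gain reduction applied to the naive filter in the reduced_gain condition.
REDUCED_GAIN_FACTOR = 1.0 / 20.0


@dataclass(frozen=True)
class PerturbationProfile:
    """External torque as a piecewise-linear function of time.

    ``times``/``values`` are the breakpoints (Nm); the profile is 0 before
    the first breakpoint and holds the last value afterwards.
    """

    kind: str
    times: np.ndarray
    values: np.ndarray
    onset: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or t.size < 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) < 0):
            raise ValueError("breakpoint times must be nondecreasing")
        if not (np.isfinite(t).all() and np.isfinite(v).all()):
            raise ValueError("profile breakpoints must be finite")
        if t.size and v[0] != 0.0 and t[0] > 0:
            pass  # interp handles the left plateau via the explicit 0 point
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        out = np.interp(t, self.times, self.values,
                        left=0.0, right=self.values[-1])
        return float(out) if np.isscalar(t) else out

    @property
    def support_end(self) -> float:
        return float(self.times[-1])


def make_profile(kind: str, magnitude: float = 2.0, onset: float = 0.0,
                 scale: float = 1.0,
                 times: np.ndarray | None = None,
                 values: np.ndarray | None = None) -> PerturbationProfile:
    """Standard perturbation profiles.

    ``step``: linear build-up over 5 ms to ``magnitude`` Nm.
    ``ramp_down``: 0 -> 3 Nm in 5 ms, then 3 -> 1 Nm over 50 ms.
    ``ramp_up``: 0 -> 1 Nm in 5 ms, then 1 -> 3 Nm over 50 ms.
    ``custom``: explicit breakpoints (``times``, ``values``).

    ``scale`` multiplies all torque levels (e.g. 0.8 for the
    reduced-magnitude variants: steps of 0.8/1.6/2.4 Nm and a ramp-up from
    0.8 to 2.4 Nm).
    """
    if kind == "step":
        t = np.array([0.0, 0.005])
        v = np.array([0.0, magnitude]) * scale
    elif kind == "ramp_down":
        t = np.array([0.0, 0.005, 0.055])
        v = np.array([0.0, 3.0, 1.0]) * scale
    elif kind == "ramp_up":
        t = np.array([0.0, 0.005, 0.055])
        v = np.array([0.0, 1.0, 3.0]) * scale
    elif kind == "custom":
        if times is None or values is None:
            raise ValueError("custom profile requires times and values")
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float) * scale
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}; "
                         f"expected step|ramp_down|ramp_up|custom")
    return PerturbationProfile(kind=kind, times=t + onset, values=v,
                               onset=onset)


def null_profile() -> PerturbationProfile:
    """Zero external torque (unperturbed posture)."""
    return PerturbationProfile(kind="custom", times=np.array([0.0]),
                               values=np.array([0.0]), onset=0.0)


@dataclass(frozen=True)
class TrialConfig:
    """Everything one closed-loop trial needs."""

    params: ModelParams = ModelParams()
    noise: NoiseSpec = NoiseSpec()
    cost: CostSpec = CostSpec()
    profile: PerturbationProfile = field(default_factory=null_profile)
    condition: str = "delay_aware"
    duration: float = 1.5
    noise_on: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, "
                             f"got {self.condition!r}")
        if self.duration < self.profile.support_end:
            raise ValueError("duration must cover the perturbation profile")


@dataclass
class SimulationTrace:
    """Time-indexed record of one closed-loop trial.

    ``x`` holds the true current-time state (n x 5), ``x_hat`` the newest
    block of the estimate, ``u`` the control sequence, ``y`` the (delayed,
    noisy) observations.  ``abort_step`` is the step index at which the
    state left the finite/bounded domain, or ``None`` for a completed
    trial; aborted trials keep the samples computed up to that step.
    """

    t: np.ndarray
    x: np.ndarray
    x_hat: np.ndarray
    u: np.ndarray
    y: np.ndarray
    condition: str
    onset: float
    dt: float
    abort_step: int | None = None

    @property
    def theta(self) -> np.ndarray:
        return self.x[:, IDX_THETA]

    @property
    def theta_dot(self) -> np.ndarray:
        return self.x[:, IDX_THETA_DOT]

    @property
    def target(self) -> float:
        return float(self.x[0, IDX_TARGET])

    @property
    def displacement(self) -> np.ndarray:
        """Joint displacement from the pre-perturbation angle (rad)."""
        return self.theta - self.x[0, IDX_THETA]

    @property
    def effective_onset(self) -> float | None:
        """Time of the first nonzero external-torque sample.

        With left-edge sample-and-hold the torque becomes nonzero one step
        after the profile's nominal onset; response windows are referenced
        to this effective onset.  ``None`` for unperturbed trials.
        """
        nz = np.nonzero(self.x[:, IDX_TE])[0]
        return float(self.t[nz[0]]) if nz.size else None

    def to_frame(self) -> pd.DataFrame:
        flag = np.zeros(len(self.t), dtype=int)
        if self.abort_step is not None:
            flag[:] = 1
        return pd.DataFrame({
            "time_s": self.t,
            "theta_rad": self.x[:, IDX_THETA],
            "theta_dot": self.x[:, IDX_THETA_DOT],
            "T_C": self.x[:, IDX_TC],
            "T_E": self.x[:, IDX_TE],
            "theta_hat": self.x_hat[:, IDX_THETA],
            "theta_dot_hat": self.x_hat[:, IDX_THETA_DOT],
            "T_E_hat": self.x_hat[:, IDX_TE],
            "u": self.u,
            "unstable_flag": flag,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _build_loop(config: TrialConfig):
    """Shared assembly: systems, filter and control law for a condition."""
    params = config.params
    block = discretize(params)
    aug = augment(block, params.delay_steps)
    law = lqr_gains(aug, config.cost)
    cond = config.condition
    if cond == "delay_aware":
        kf = KalmanFilter(aug, config.noise)
    elif cond == "naive":
        kf = KalmanFilter(block, config.noise)
    elif cond == "reduced_gain":
        kf = KalmanFilter(block, scale_feedback_weight(
            config.noise, REDUCED_GAIN_FACTOR))
    else:  # perfect_state
        kf = None
    return block, aug, law, kf


def run_trial(config: TrialConfig,
              law: ControlLaw | None = None,
              kf: KalmanFilter | None = None) -> SimulationTrace:
    """Simulate one closed-loop trial.

    Per step: the profile-driven external torque is written into the true
    state, the delayed observation is formed, the estimator for the chosen
    condition is updated, and the control ``u = -L z_hat`` is applied.
    Noise draws follow a fixed order (motor, prediction, measurement) from
    one seeded generator, so a config is bitwise reproducible.
    """
    params = config.params
    if law is None or (kf is None and config.condition != "perfect_state"):
        block, aug, law_built, kf_built = _build_loop(config)
        law = law if law is not None else law_built
        kf = kf if kf is not None else kf_built
    else:
        block = discretize(params)
        aug = augment(block, params.delay_steps)
    n_aug = aug.dim
    h = params.delay_steps
    dt = params.dt
    n_steps = int(round(config.duration / dt)) + 1
    rng = np.random.default_rng(config.seed)

    x0 = np.zeros(STATE_DIM)
    x0[IDX_THETA] = params.target_rad
    x0[IDX_TARGET] = params.target_rad
    z = np.tile(x0, h + 1)

    cond = config.condition
    if cond == "perfect_state":
        est = None
    elif cond == "delay_aware":
        est = kf.init_state(z0=z)
    else:
        est = kf.init_state(z0=x0)

    sig_m = np.sqrt(config.noise.sigma_motor) if config.noise_on else 0.0
    sig_p = np.sqrt(config.noise.sigma_pred) if config.noise_on else 0.0
    sig_o = np.sqrt(config.noise.sigma_meas) if config.noise_on else 0.0

    t_grid = np.arange(n_steps) * dt
    te_seq = np.asarray(config.profile(t_grid))
    nz = np.nonzero(te_seq)[0]
    first_pert = int(nz[0]) if nz.size else None

    X = np.zeros((n_steps, STATE_DIM))
    Xh = np.zeros((n_steps, STATE_DIM))
    U = np.zeros(n_steps)
    Y = np.zeros((n_steps, STATE_DIM))
    abort_step = None
    u_prev = 0.0

    for k in range(n_steps):
        z[IDX_TE] = te_seq[k]
        x_true = z[:STATE_DIM]
        if not np.isfinite(x_true).all() or abs(x_true[IDX_THETA]) > ABORT_ANGLE_RAD:
            abort_step = k
            break

        # fixed draw order: motor, prediction, measurement
        xi = rng.normal(0.0, 1.0) * sig_m
        if config.noise.pred_noise_full and kf is not None:
            zeta = rng.normal(0.0, 1.0, kf.dim) * sig_p
        else:
            zeta = np.zeros(kf.dim if kf is not None else n_aug)
            zeta[:STATE_DIM] = rng.normal(0.0, 1.0, STATE_DIM) * sig_p
        omega = rng.normal(0.0, 1.0, STATE_DIM) * sig_o

        y = aug.oldest(z) + omega
        Y[k] = y

        if cond == "perfect_state":
            x_hat = x_true.copy()
            if first_pert is not None and first_pert <= k < first_pert + h:
                u = 0.0
            else:
                u = float(-(law.gain_at(k)[:STATE_DIM] @ x_true))
        else:
            if k > 0:
                est = kf.step(est, u_prev, y, pred_noise=zeta)
            x_hat = est.z_hat[:STATE_DIM].copy()
            if cond == "delay_aware":
                u = law.control(est.z_hat, k)
            else:
                u = float(-(law.gain_at(k)[:STATE_DIM] @ est.z_hat))

        X[k] = x_true
        Xh[k] = x_hat
        U[k] = u

        z = aug.A @ z + aug.B[:, 0] * (u + xi)
        u_prev = u

    if abort_step is not None:
        sl = slice(0, abort_step)
        return SimulationTrace(t=t_grid[sl], x=X[sl], x_hat=Xh[sl], u=U[sl],
                               y=Y[sl], condition=cond,
                               onset=config.profile.onset, dt=dt,
                               abort_step=abort_step)
    return SimulationTrace(t=t_grid, x=X, x_hat=Xh, u=U, y=Y, condition=cond,
                           onset=config.profile.onset, dt=dt)


def closed_loop_transition(config: TrialConfig) -> np.ndarray:
    """Transition matrix of the noise-free joint plant-estimator loop.

    Stacks the true augmented state with the estimator state and assembles
    the one-step map under ``u = -L z_hat`` (or ``u = -L x`` for the
    perfect-state condition).  The spectral radius of this matrix, with
    the structural constant coordinates excluded, decides closed-loop
    stability analytically.
    """
    block, aug, law, kf = _build_loop(config)
    L_aug = law.L[None, :]
    n = aug.dim
    if config.condition == "perfect_state":
        return aug.A - aug.B @ L_aug
    if config.condition == "delay_aware":
        A, B, H, K = aug.A, aug.B, aug.H, kf.K_ss
        # z' = A z - B L zh ; zh' = K H z' + (I - K H)(A - B L) zh
        M = np.zeros((2 * n, 2 * n))
        M[:n, :n] = A
        M[:n, n:] = -B @ L_aug
        M[n:, :n] = K @ H @ A
        M[n:, n:] = (np.eye(n) - K @ H) @ (A - B @ L_aug) - K @ H @ B @ L_aug
        return M
    # naive / reduced_gain: 5-state filter fed the physically delayed signal
    A5, B5, K5 = block.A, block.B, kf.K_ss
    L5 = L_aug[:, :STATE_DIM]
    Acl5 = A5 - B5 @ L5
    M = np.zeros((n + STATE_DIM, n + STATE_DIM))
    M[:n, :n] = aug.A
    M[:n, n:] = -aug.B @ L5
    M[n:, :n] = K5 @ aug.H @ aug.A
    M[n:, n:] = (np.eye(STATE_DIM) - K5) @ Acl5 - K5 @ aug.H @ aug.B @ L5
    return M


def closed_loop_spectral_radius(config: TrialConfig) -> float:
    """Stability margin of a condition: spectral radius of the assembled
    closed-loop transition, structural constants excluded."""
    from .control import stability_spectral_radius
    return stability_spectral_radius(closed_loop_transition(config))


def run_batch(config: TrialConfig, n_trials: int,
              seeds: list[int] | None = None,
              ) -> tuple[SimulationTrace, list[SimulationTrace]]:
    """Run ``n_trials`` seeded trials and return (mean trace, trials).

    Per-trial seeds default to ``base seed + index``.  The mean trace is
    the pointwise average of the per-trial states/estimates/controls; a
    batch containing an aborted trial averages over the shortest common
    length.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if seeds is None:
        seeds = [config.seed + i for i in range(n_trials)]
    if len(seeds) != n_trials:
        raise ValueError("seeds must match n_trials")
    # gains depend only on the config, not the seed: compute once
    _, _, law, kf = _build_loop(config)
    traces = [run_trial(replace(config, seed=s), law=law, kf=kf)
              for s in seeds]
    n = min(len(tr.t) for tr in traces)
    mean = SimulationTrace(
        t=traces[0].t[:n],
        x=np.mean([tr.x[:n] for tr in traces], axis=0),
        x_hat=np.mean([tr.x_hat[:n] for tr in traces], axis=0),
        u=np.mean([tr.u[:n] for tr in traces], axis=0),
        y=np.mean([tr.y[:n] for tr in traces], axis=0),
        condition=config.condition,
        onset=config.profile.onset,
        dt=config.params.dt,
        abort_step=None if all(tr.abort_step is None for tr in traces)
        else n,
    )
    return mean, traces


def run_reaching(amplitudes_deg, params: ModelParams = ModelParams(),
                 noise: NoiseSpec = NoiseSpec(), condition: str = "delay_aware",
                 w: float | None = None, r: float | None = None,
                 free_s: float = 0.6, penalized_s: float = 0.4,
                 noise_on: bool = False, seed: int = 0,
                 ) -> list[SimulationTrace]:
    """Reaching movements under a two-phase cost.

    The joint is free to move for ``free_s`` (position weight 0), then
    deviations from the prescribed angle are penalized for ``penalized_s``.
    Returns one trace per amplitude (degrees).
    """
    if len(amplitudes_deg) == 0:
        raise ValueError("amplitudes list must be nonempty")
    from .control import DEFAULT_R, DEFAULT_W
    w = DEFAULT_W if w is None else w
    r = DEFAULT_R if r is None else r
    dt = params.dt
    n_free = int(round(free_s / dt))
    n_pen = int(round(penalized_s / dt))
    horizon = n_free + n_pen
    cost = CostSpec(w=w, r=r, horizon=horizon,
                    penalty_window=(n_free, horizon))
    traces = []
    for amp in amplitudes_deg:
        target = np.deg2rad(amp)
        p = ModelParams(inertia=params.inertia, viscosity=params.viscosity,
                        tau=params.tau, dt=params.dt,
                        delay_steps=params.delay_steps, target_rad=target)
        block = discretize(p)
        aug = augment(block, p.delay_steps)
        law = lqr_schedule(aug, cost)
        cfg = TrialConfig(params=p, noise=noise, cost=cost,
                          profile=null_profile(), condition=condition,
                          duration=horizon * dt, noise_on=noise_on, seed=seed)
        # start at angle 0 with the target at `amp`: shift the initial state
        tr = _run_reaching_trial(cfg, law, aug, block)
        traces.append(tr)
    return traces


def _run_reaching_trial(config: TrialConfig, law: ControlLaw,
                        aug: AugmentedLinearSystem, block: LinearSystem,
                        ) -> SimulationTrace:
    """Reaching trial: initial angle 0, target at ``params.target_rad``."""
    params = config.params
    h = params.delay_steps
    dt = params.dt
    n_steps = int(round(config.duration / dt)) + 1
    rng = np.random.default_rng(config.seed)
    cond = config.condition

    x0 = np.zeros(STATE_DIM)
    x0[IDX_TARGET] = params.target_rad
    z = np.tile(x0, h + 1)
    if cond == "delay_aware" or cond == "perfect_state":
        kf = KalmanFilter(aug, config.noise) if cond == "delay_aware" else None
    else:
        noise = config.noise if cond == "naive" else scale_feedback_weight(
            config.noise, REDUCED_GAIN_FACTOR)
        kf = KalmanFilter(block, noise)
    if cond == "perfect_state":
        est = None
    elif cond == "delay_aware":
        est = kf.init_state(z0=z)
    else:
        est = kf.init_state(z0=x0)

    sig_m = np.sqrt(config.noise.sigma_motor) if config.noise_on else 0.0
    sig_p = np.sqrt(config.noise.sigma_pred) if config.noise_on else 0.0
    sig_o = np.sqrt(config.noise.sigma_meas) if config.noise_on else 0.0

    X = np.zeros((n_steps, STATE_DIM))
    Xh = np.zeros((n_steps, STATE_DIM))
    U = np.zeros(n_steps)
    Y = np.zeros((n_steps, STATE_DIM))
    u_prev = 0.0
    for k in range(n_steps):
        x_true = z[:STATE_DIM]
        xi = rng.normal(0.0, 1.0) * sig_m
        zeta = np.zeros(kf.dim if kf is not None else aug.dim)
        zeta[:STATE_DIM] = rng.normal(0.0, 1.0, STATE_DIM) * sig_p
        omega = rng.normal(0.0, 1.0, STATE_DIM) * sig_o
        y = aug.oldest(z) + omega
        Y[k] = y
        if cond == "perfect_state":
            x_hat = x_true.copy()
            u = float(-(law.gain_at(k)[:STATE_DIM] @ x_true))
        else:
            if k > 0:
                est = kf.step(est, u_prev, y, pred_noise=zeta)
            x_hat = est.z_hat[:STATE_DIM].copy()
            if cond == "delay_aware":
                u = law.control(est.z_hat, k)
            else:
                u = float(-(law.gain_at(k)[:STATE_DIM] @ est.z_hat))
        X[k] = x_true
        Xh[k] = x_hat
        U[k] = u
        z = aug.A @ z + aug.B[:, 0] * (u + xi)
        u_prev = u
    t = np.arange(n_steps) * dt
    return SimulationTrace(t=t, x=X, x_hat=Xh, u=U, y=Y, condition=cond,
                           onset=0.0, dt=dt)
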