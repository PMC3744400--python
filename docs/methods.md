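# Methods

## Plant and discretization

The joint is a rigid body rotating in the horizontal plane:
`I θ̈ = T_C + T_E − G θ̇`, with the controlled torque following the
control signal through a first-order muscle-like low-pass,
`τ Ṫ_C = u − T_C`. Defaults: `I = 0.065 kg·m²`, `G = 0.05 N·m·s/rad`,
`τ = 60 ms`. The printed unit of the viscous constant in the source
physiology ("N/s") is dimensionally ambiguous; it is implemented as a
torque per unit angular velocity (N·m·s/rad), the only reading consistent
with the equation of motion. The state block is
`x = (θ, θ̇, T_C, T_E, θ*)`: the external torque and the target are
carried as constant state entries so that disturbance rejection and
tracking are linear in the state. Angles are radians internally; degrees
appear only at reporting boundaries. The model is sign-symmetric, so
"flexion/extension" is presentation only.

Discretization is explicit Euler at `dt = 10 ms` (`A = I + dt·J`, with
the Jacobian evaluated at the old state, the standard explicit scheme).
The feedback delay is `h = 6` steps = 60 ms, a long-latency transmission
delay plus one step to reflect that the controller, unlike muscle, acts
instantaneously.

## Delay augmentation and estimation

The augmented state `z_t = (x_t, …, x_{t−h})` (dimension 35 at the
defaults) makes the delayed observation memoryless: `y_t = H z_t + ω_t`
with `H` selecting the oldest block. The transition propagates the newest
block by the plant dynamics and shifts the history blocks down by one.

The Kalman filter on this system is the delay-compensating estimator.
Noise model: motor noise `ξ` (variance `σ_ξ² = 10⁻⁶`) enters through the
control channel; measurement noise `ω` (variance `σ_ω² = 10⁻⁶`) affects
all five observed entries; prediction noise `ζ` (variance
`σ_ζ² = 10⁻⁶`) corrupts the prior estimate. The filter's process-noise
covariance is `B σ_ξ² Bᵀ` plus `σ_ζ²` on the diagonal of the newest block
— `ζ` corrupts the prediction of the *new* state; a full-diagonal
placement is exposed as a config flag (`pred_noise_full`) since the exact
covariance structure of the prediction noise over the augmented state is
a modelling choice. All variances are per-step quantities on the 10 ms
grid.

Gains are computed at steady state: the prior-covariance recursion is
iterated to a fixed point (successive-iterate norm < 1e-12, capped at
10⁵ iterations, failure reported with the last residual). Steady-state
gains match a stationary postural task; the exact time-varying filter is
retained (`steady_state=False`) and is the object compared against batch
joint-Gaussian conditioning in the tests. Gains are computed once at the
`T_E = 0` initial condition and reused when the external torque changes
mid-trial; with purely additive noise this has no effect on the
closed-loop statistics.

Because each innovation multiplies a gain with nonzero rows in every
block, one observation simultaneously corrects the present *and* the
stored past states — the mechanism by which the estimate of a just-
arrived perturbation propagates forward through the delay interval. Under
the constant-torque internal model, the estimated `T_E` is a delayed,
filtered copy of the true torque; perturbation profiles that mimic a
larger (smaller) step during the delay produce transient over-
(under-)estimation of displacement. An optional affine drift of the
internal torque model (`te_slope` on the filter) implements a
linear-ramp prior; it is off by default.

Two degraded estimators are included for comparison. The *naive* filter
runs on the non-augmented 5-state model and treats the physically delayed
measurement as current; at the default parameters the assembled loop has
spectral radius 1.17 and diverges after a 2 Nm step. The *reduced-gain*
variant multiplies the naive filter's converged Kalman gain by 1/20 —
implemented as a deterministic gain scaling rather than by inflating
`σ_ω²`, for reproducibility — which restores stability (spectral radius
0.97) at the cost of a settling time an order of magnitude longer.

## Control

The cost is `Σ_{t<N} [w_t (θ_t − θ*)² + R u_t²]` with terminal control
weight zero. Only the position deviation is penalized; velocity or torque
penalties are not used. Certainty equivalence holds for this model class,
so the law is computed independently of the noise. For postural tasks the
backward Riccati recursion is iterated until the gain is constant
(sustained gain change < 1e-10); convergence is judged on a sustained
streak of converged gain updates because the gain stalls at exactly zero
for the first few backward steps and the Riccati matrix drifts forever in
the uncontrollable constant directions (`T_E`, `θ*`). Because the cost
involves only the newest block, which evolves autonomously, the augmented
gain provably reduces to the 5-state gain padded with zeros (asserted in
the tests). Reaching movements use the explicit finite-horizon schedule
with a two-phase cost: 600 ms free (`w = 0`), then 400 ms of position
penalty toward targets of 10/15/20°.

The cost weights are not physical constants; they were calibrated once —
`w = 1`, `R = 2×10⁻⁵` — so that the noise-free 2 Nm step response
returns within the task's 800 ms instruction window as a single smooth
excursion (measured settling: 190 ms; peak 6.5° at 110 ms) and the
unperturbed postural sway sits near 0.1° SD per 100 ms window at the
default noise level (measured: ≈0.085°). Both weights are config-exposed;
the qualitative results (stability dichotomy, reversal-time ordering)
hold across at least two orders of magnitude of `R`.

## Simulation conditions

Perturbation profiles are piecewise-linear in continuous time (step:
build-up to the magnitude in 5 ms; ramp-down: 0→3 Nm in 5 ms then 3→1 Nm
in 50 ms; ramp-up: 0→1 Nm in 5 ms then 1→3 Nm in 50 ms; a `scale` factor
produces the reduced-magnitude variants). Profiles are sampled at the
left edge of each interval (sample-and-hold), so on the 10 ms grid the
5 ms build-up collapses into one step and the torque becomes nonzero one
step after the nominal onset. All response windows are therefore
referenced to the *effective onset* — the first nonzero torque sample —
which the trace records. A finer simulation grid is available through
`ModelParams.dt` for convergence checks.

Per step the engine draws noise in a fixed order (motor, prediction,
measurement) from one seeded generator, writes the profile torque into
the true state, forms the delayed observation, updates the estimator of
the chosen condition, and applies the control. Batches seed trial `i`
with `base + i`. The `perfect_state` condition zeroes the control for one
feedback delay after the effective onset and then applies the unchanged
feedback gains to the true state — an ideal-estimator benchmark whose
artificial delay makes its step-response reversal times match the
delay-aware condition, isolating the estimator's contribution to the
ramp-profile effects. A trial whose state leaves the finite domain (or
exceeds 10⁶ rad) is truncated at that step and carries the abort index;
stability classification treats such traces as unstable.

Default durations: 1.5 s for perturbation trials, 3 s for stability
classification, 20 s for the postural-variability figure; these are
declared choices, not values inherited from any experiment.

## Outcome measures

*Reversal time*: first sample attaining the maximum absolute displacement
within 0–500 ms of the effective onset (ties to the earliest sample); a
displacement still growing at the window edge yields a distinguished
no-reversal result. Times can be re-referenced to the mean across step
responses. An optional 50 Hz dual-pass 4th-order Butterworth low-pass
mirrors the treatment of recorded kinematics and is off by default for
model traces. The Cartesian hand-speed minimum reduces, for a one-link
geometry, to a joint-speed minimum and is provided under that name.

*Stability*: stable iff the displacement is finite throughout and the
angle varies by less than 1° over the final 500 ms of a ≥3 s trace;
diagnostics include velocity zero crossings, the trend of successive
displacement peaks, and the spectral radius of the assembled
plant-estimator transition with the two structurally constant
coordinates (`T_E`, `θ*`) excluded — they contribute exact unit
eigenvalues that say nothing about loop stability.

*ROC divergence onset*: per-sample area under the ROC curve
(rank-statistic form, direction-agnostic) between two trial ensembles;
the onset is the first time the AUC exceeds 0.75 and persists for 25 ms.
The criterion values follow common practice for perturbation-evoked EMG
— the threshold and persistence are conventions, and both are exposed. A
differential mode discriminates the paired difference signal from its
own pre-perturbation (−50–0 ms) distribution.

*Epoch statistics*: per-trial mean activity in the classical windows
(Pre −50–0, R1 20–45, R2 45–75, R3 75–105, early voluntary 120–180 ms),
half-open `[start, end)` to resolve the shared 45 ms boundary, with
one-tailed paired t tests across trial pairs; identical pairs report
`t = 0, p = 0.5` rather than a 0/0 failure.

## Synthetic EMG

The generator emulates 1 kHz rectified-EMG envelopes: a tonic baseline
(1 in units normalized to a background-load reference), trapezoidal
response components in the classical latency windows, a per-trial
multiplicative gain ~ N(1, 0.1), and additive envelope noise
(SD 0.1), floored at zero after the noise is added (so tests can state
the rectification exactly). Divergence experiments pair two specs
identical up to a ground-truth time; the separation can be specified as
an SNR defined against the *total* between-trial envelope SD at the
divergence time (additive noise plus the gain contribution), which is
the spread an onset detector actually has to beat. The preprocessing
chain (10–400 Hz dual-pass band-pass, rectification, normalization by a
background reference passed through the same chain) mirrors standard EMG
conditioning.

What the generator does not emulate: motor-unit biophysics, within-trial
autocorrelation of the envelope beyond the component shapes,
signal-dependent noise, or the force–EMG mapping. Passing the ROC and
epoch tests therefore demonstrates correctness of the analysis
operations under a known ground truth, not performance on recorded
muscle activity.

## Numerical choices and limitations

- Covariance iterations are symmetrized each step; PSD is enforced only
  through the update form (smallest eigenvalue ≥ −1e-10 asserted in
  tests).
- With extremely uninformative measurements (`σ_ω² ≫ 1`) the covariance
  recursion converges too slowly to reach the 1e-12 fixed-point
  tolerance within the iteration cap; the gain→0 limit is exercised at
  moderate noise levels instead.
- The linear model omits gravity, two-joint interaction torques, tendon
  and activation nonlinearities, and signal-dependent noise. The
  superposition property (exact scaling of step responses) is a
  statement about this linear model; recorded reversal times deviate
  from exact invariance at the largest loads.
- The naive-estimator instability is a property of the default gain
  calibration; sufficiently weak feedback (the 1/20 gain scaling) is
  stable by construction, which is the point of that comparison.
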