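"""Synthetic rectified-EMG trial ensembles.

Emulates the statistical shape of perturbation-evoked surface EMG sampled
at 1 kHz: a tonic baseline, stereotyped response components in the
classical latency windows (short-latency around 20-45 ms, long-latency
45-105 ms, early voluntary beyond 120 ms), trial-to-trial gain variability
and additive envelope noise.  Every ensemble can carry a ground-truth
divergence time, so onset-detection operations are testable end to end
without any recorded data.

This is a phenomenological envelope model for exercising analysis code —
not a biophysical simulation of motor units, and not a claim about any
particular muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .analysis import TrialEnsemble


@dataclass(frozen=True)
class ResponseComponent:
    """One trapezoidal burst: linear rise over ``rise_s`` starting at
    ``onset_s``, plateau until ``onset_s + duration_s``, linear fall over
    ``rise_s``."""

    onset_s: float
    amplitude: float
    rise_s: float = 0.010
    duration_s: float = 0.030

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("component onset must be nonnegative")
        if not np.isfinite(self.amplitude):
            raise ValueError("component amplitude must be finite")
        if self.rise_s <= 0 or self.duration_s < 0:
            raise ValueError("rise must be > 0 and duration >= 0")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        up = np.clip((t - self.onset_s) / self.rise_s, 0.0, 1.0)
        down = np.clip((t - self.onset_s - self.duration_s) / self.rise_s,
                       0.0, 1.0)
        return self.amplitude * (up - down)


#: Component layout loosely following the classical response epochs.
DEFAULT_COMPONENTS = (
    ResponseComponent(onset_s=0.020, amplitude=1.0, duration_s=0.025),
    ResponseComponent(onset_s=0.045, amplitude=2.0, duration_s=0.060),
    ResponseComponent(onset_s=0.120, amplitude=1.5, duration_s=0.060),
)


@dataclass(frozen=True)
class EmgSpec:
    """Recipe for one synthetic trial ensemble.

    Each trial is ``(baseline + sum of components) * gain + noise``,
    floored at zero (rectification after noise addition).  ``gain`` is a
    per-trial multiplicative factor ~ N(1, gain_sd); the additive noise is
    white Gaussian on the envelope with SD ``noise_sd``.  Levels are in
    normalized units (1 = activity against the background load).  The time
    grid spans ``t_start`` to ``t_stop`` at ``fs``; perturbation onset is
    time 0, so the pre-perturbation baseline window is included.
    """

    fs: float = 1000.0
    n_trials: int = 20
    baseline: float = 1.0
    components: tuple[ResponseComponent, ...] = DEFAULT_COMPONENTS
    noise_sd: float = 0.1
    gain_sd: float = 0.1
    t_start: float = -0.100
    t_stop: float = 0.300
    divergence_time: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.noise_sd < 0 or self.gain_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.t_stop <= self.t_start:
            raise ValueError("t_stop must exceed t_start")

    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) * self.fs)) + 1
        return self.t_start + np.arange(n) / self.fs

    def template(self) -> np.ndarray:
        """Noiseless envelope (baseline plus components) on the grid."""
        t = self.time_grid()
        out = np.full(t.shape, float(self.baseline))
        for comp in self.components:
            out += comp.evaluate(t)
        return out


def generate_ensemble(spec: EmgSpec) -> TrialEnsemble:
    """Draw one trial ensemble from a spec (same seed, same ensemble)."""
    rng = np.random.default_rng(spec.seed)
    t = spec.time_grid()
    template = spec.template()
    gains = rng.normal(1.0, spec.gain_sd, size=spec.n_trials)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_trials, t.size))
    data = np.maximum(gains[:, None] * template[None, :] + noise, 0.0)
    return TrialEnsemble(t=t, data=data, condition="synthetic",
                         divergence_time=spec.divergence_time)


def trial_sd_at(spec: EmgSpec, t: float) -> float:
    """Between-trial SD of the envelope at time ``t``: additive noise plus
    the multiplicative-gain contribution ``gain_sd * template(t)``."""
    grid = spec.time_grid()
    tmpl = spec.template()
    k = int(np.argmin(np.abs(grid - t)))
    return float(np.hypot(spec.noise_sd, spec.gain_sd * tmpl[k]))


def diverging_pair(base: EmgSpec, divergence_s: float,
                   separation: float | None = None,
                   snr: float | None = None,
                   seed_b: int | None = None) -> tuple[EmgSpec, EmgSpec]:
    """Two specs identical up to ``divergence_s``, separated afterwards.

    The second spec adds a sustained component from the divergence time to
    the end of the grid.  Its amplitude is ``separation`` (normalized
    units) or, when ``snr`` is given instead, ``snr`` times the between-
    trial SD of the envelope at the divergence time (additive noise and
    gain variability combined — the spread an onset detector actually has
    to beat).  Both specs carry the ground-truth divergence time; the
    second draws fresh noise from ``seed_b`` (default ``base.seed + 1``).
    """
    if (separation is None) == (snr is None):
        raise ValueError("give exactly one of separation or snr")
    if snr is not None:
        separation = snr * trial_sd_at(base, divergence_s)
    extra = ResponseComponent(
        onset_s=divergence_s, amplitude=separation, rise_s=0.005,
        duration_s=max(base.t_stop - divergence_s, 0.0))
    a = replace(base, divergence_time=divergence_s)
    b = replace(base, components=base.components + (extra,),
                divergence_time=divergence_s,
                seed=base.seed + 1 if seed_b is None else seed_b)
    return a, b


def preprocess_emg(raw: TrialEnsemble,
                   background: TrialEnsemble | float,
                   band: tuple[float, float] = (10.0, 400.0),
                   order: int = 4, average: bool = False) -> TrialEnsemble:
    """The standard EMG conditioning chain.

    Band-pass (dual-pass Butterworth, zero phase), full-wave rectify,
    optionally average across trials, and normalize by the mean activity
    of a background-load reference passed through the same chain (a
    signal equal to the reference therefore normalizes to mean 1).
    ``background`` may also be a precomputed scalar reference level.
    """
    lo, hi = band
    if raw.fs < 2 * hi:
        raise ValueError(
            f"sampling rate {raw.fs:.0f} Hz too low for a {hi:.0f} Hz band edge")
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=raw.fs,
                        output="sos")
    data = np.abs(signal.sosfiltfilt(sos, raw.data, axis=1))
    if isinstance(background, TrialEnsemble):
        bg = np.abs(signal.sosfiltfilt(sos, background.data, axis=1))
        ref = float(bg.mean())
    else:
        ref = float(background)
    if ref <= 0:
        raise ValueError("background reference level must be positive")
    data = data / ref
    if average:
        data = data.mean(axis=0, keepdims=True)
    return TrialEnsemble(t=raw.t, data=data, condition=raw.condition,
                         divergence_time=raw.divergence_time)
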