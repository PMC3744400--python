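"""Outcome measures on simulation traces and trial ensembles.

Trace-level measures mirror how perturbation responses are quantified in
upper-limb experiments: the reversal time (time of maximum joint
displacement, marking the turnaround of the corrective movement), the
estimation-error time series (estimate minus truth), settling time, and a
stability classification.  Ensemble-level measures operate on trial x time
tables (EMG-like or kinematic): ROC-based divergence onset between two
ensembles and mean activity in the classical response epochs (R1/R2/R3,
early voluntary) with one-tailed paired t statistics.

All response windows are referenced to the perturbation onset carried by
the trace or supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .simulate import SimulationTrace

#: Classical EMG response epochs, seconds relative to perturbation onset.
#: Intervals are half-open [start, end), which resolves the shared 45 ms
#: boundary between the short- and long-latency windows.
EPOCHS: dict[str, tuple[float, float]] = {
    "pre": (-0.050, 0.0),
    "r1": (0.020, 0.045),
    "r2": (0.045, 0.075),
    "r3": (0.075, 0.105),
    "voluntary": (0.120, 0.180),
}


# ---------------------------------------------------------------------------
# trial ensembles

@dataclass
class TrialEnsemble:
    """A rectangular trial x time table with a shared time grid.

    ``data`` has shape (n_trials, n_samples); ``t`` is strictly
    increasing, typically at 1 kHz for EMG-like signals.
    ``divergence_time`` optionally carries the generator's ground-truth
    time at which this ensemble starts to differ from a sibling.
    """

    t: np.ndarray
    data: np.ndarray
    condition: str = ""
    divergence_time: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.t.ndim != 1 or self.data.shape[1] != self.t.size:
            raise ValueError("data must be (n_trials, len(t))")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def fs(self) -> float:
        """Sampling rate (Hz), from the median grid step."""
        return 1.0 / float(np.median(np.diff(self.t)))

    def mean(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"trial_{i:03d}": self.data[i] for i in range(self.n_trials)}
        return pd.DataFrame({"time_s": self.t, **cols})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition: str = "") -> "TrialEnsemble":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError("ensemble CSV must have a time_s column")
        trial_cols = [c for c in df.columns if c.startswith("trial_")]
        if not trial_cols:
            raise ValueError("ensemble CSV must have trial_NNN columns")
        return cls(t=df["time_s"].to_numpy(),
                   data=df[trial_cols].to_numpy().T, condition=condition)


# ---------------------------------------------------------------------------
# trace-level measures

def lowpass_kinematics(x: np.ndarray, fs: float, cutoff: float = 50.0,
                       order: int = 4) -> np.ndarray:
    """Dual-pass Butterworth low-pass, as applied to recorded kinematics."""
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _onset(trace: SimulationTrace, onset: float | None) -> float:
    if onset is not None:
        return onset
    eff = trace.effective_onset
    if eff is None:
        raise ValueError("trace has no perturbation; pass onset explicitly")
    return eff


def reversal_time(trace: SimulationTrace, window: float = 0.5,
                  onset: float | None = None, lowpass: bool = False,
                  reference: float = 0.0) -> float | None:
    """Time of maximum joint displacement after the perturbation.

    Returns the first sample (seconds relative to onset) attaining the
    maximum absolute displacement within ``window`` seconds after the
    (effective) perturbation onset — the point where the perturbation-
    evoked motion reverses toward the target.  Ties break to the earliest
    sample.  A displacement still growing at the window edge has not
    reversed: the result is ``None`` rather than a number.

    ``reference`` is subtracted from the result, re-referencing the time
    to e.g. the mean reversal time across step responses.  ``lowpass``
    applies the 50 Hz dual-pass filter used for recorded kinematics (off
    by default: model traces are already smooth).
    """
    t0 = _onset(trace, onset)
    disp = np.abs(trace.displacement)
    if lowpass:
        disp = np.abs(lowpass_kinematics(trace.displacement, 1.0 / trace.dt))
    mask = (trace.t >= t0) & (trace.t <= t0 + window)
    if not mask.any():
        raise ValueError("reversal window lies outside the trace")
    idx = np.flatnonzero(mask)
    d = disp[idx]
    k = int(np.argmax(d))
    if k == len(d) - 1 and len(d) >= 2 and d[-1] > d[-2]:
        return None  # still growing at the window edge: no reversal
    return float(trace.t[idx[k]] - t0 - reference)


def settling_time(trace: SimulationTrace, threshold_deg: float = 1.0,
                  onset: float | None = None) -> float | None:
    """First time after onset from which |displacement| stays below
    ``threshold_deg`` for the remainder of the trace; ``None`` if never."""
    t0 = _onset(trace, onset)
    disp_deg = np.abs(np.rad2deg(trace.displacement))
    below = disp_deg < threshold_deg
    start = int(np.searchsorted(trace.t, t0))
    for k in range(start, len(below)):
        if below[k:].all():
            return float(trace.t[k] - t0)
    return None


def windowed_angle_sd(trace: SimulationTrace, window_s: float = 0.1) -> float:
    """Postural variability: SD of the joint angle per consecutive window.

    Splits the angle trace into consecutive windows of ``window_s``
    seconds, computes the sample SD within each, and returns the average
    across windows, in degrees.  This is the standard summary of
    unperturbed postural sway on a short time scale.
    """
    theta_deg = np.rad2deg(trace.theta)
    n = int(round(window_s / trace.dt))
    if n < 2:
        raise ValueError("window too short for the trace's time step")
    m = theta_deg.size // n
    if m < 1:
        raise ValueError("trace shorter than one window")
    windows = theta_deg[:m * n].reshape(m, n)
    return float(np.mean(np.std(windows, axis=1, ddof=1)))


def estimation_error(trace: SimulationTrace) -> pd.DataFrame:
    """Estimate-minus-truth error sequences for angle, velocity and T_E."""
    from .dynamics import IDX_TE, IDX_THETA, IDX_THETA_DOT
    err = trace.x_hat - trace.x
    return pd.DataFrame({
        "time_s": trace.t,
        "theta_err": err[:, IDX_THETA],
        "theta_dot_err": err[:, IDX_THETA_DOT],
        "T_E_err": err[:, IDX_TE],
    })


@dataclass(frozen=True)
class StabilityResult:
    """Verdict plus diagnostics of :func:`classify_stability`."""

    stable: bool
    final_range_deg: float
    zero_crossings: int
    peak_trend: float  # >1: growing oscillation; <1: decaying
    spectral_radius: float | None = None
    aborted: bool = False


def classify_stability(trace: SimulationTrace,
                       spectral_radius: float | None = None,
                       ) -> StabilityResult:
    """Classify a closed-loop trace as stable or unstable.

    Stable means the displacement stays finite throughout and the joint
    angle varies by less than 1 degree over the final 500 ms.  A trace
    aborted mid-simulation (state left the finite domain) is unstable by
    definition.  Diagnostics: number of velocity zero crossings, the
    trend of successive displacement-peak amplitudes (last/first local
    maximum of |displacement|), and optionally the closed-loop spectral
    radius computed by :func:`delaylqg.simulate.closed_loop_spectral_radius`.
    """
    disp = trace.displacement
    vel = trace.theta_dot
    crossings = int(np.sum(np.diff(np.signbit(vel[np.abs(vel) > 0])) != 0))
    d = np.abs(disp)
    peaks, _ = signal.find_peaks(d)
    peak_trend = float(d[peaks[-1]] / d[peaks[0]]) if len(peaks) >= 2 else 0.0
    if trace.abort_step is not None or not np.isfinite(disp).all():
        return StabilityResult(stable=False, final_range_deg=np.inf,
                               zero_crossings=crossings, peak_trend=peak_trend,
                               spectral_radius=spectral_radius, aborted=True)
    if trace.t[-1] - trace.t[0] < 3.0:
        raise ValueError("stability classification needs a trace >= 3 s")
    tail = trace.t >= trace.t[-1] - 0.5
    final_range = float(np.ptp(np.rad2deg(trace.theta[tail])))
    return StabilityResult(stable=final_range < 1.0,
                           final_range_deg=final_range,
                           zero_crossings=crossings, peak_trend=peak_trend,
                           spectral_radius=spectral_radius)


# ---------------------------------------------------------------------------
# ROC divergence onset

@dataclass(frozen=True)
class RocParams:
    """Criterion for calling the onset of divergence between ensembles.

    The onset is the first time the area under the ROC curve for
    discriminating the two ensembles exceeds ``threshold`` and stays
    above it for ``persistence_s``.  The criterion (0.75 sustained for
    25 ms) follows common practice for perturbation-evoked EMG.
    ``baseline_window`` feeds the differential mode, which discriminates
    the post-onset differential signal from its own pre-perturbation
    (baseline) distribution instead of ensemble a from ensemble b.
    """

    threshold: float = 0.75
    persistence_s: float = 0.025
    baseline_window: tuple[float, float] = (-0.050, 0.0)
    differential: bool = False

    def __post_init__(self) -> None:
        if not (0.5 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0.5, 1]")
        if self.persistence_s <= 0:
            raise ValueError("persistence must be > 0")


@dataclass(frozen=True)
class RocResult:
    onset: float | None
    auc: np.ndarray = field(repr=False)
    t: np.ndarray = field(repr=False)


def _auc_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-column AUC of discriminating rows of ``b`` from rows of ``a``
    (Mann-Whitney U statistic scaled to [0, 1], ties shared)."""
    n_a, n_b = a.shape[0], b.shape[0]
    stacked = np.concatenate([a, b], axis=0)
    ranks = stats.rankdata(stacked, axis=0)
    r_b = ranks[n_a:].sum(axis=0)
    u_b = r_b - n_b * (n_b + 1) / 2.0
    return u_b / (n_a * n_b)


def roc_divergence_onset(a: TrialEnsemble, b: TrialEnsemble,
                         params: RocParams = RocParams()) -> RocResult:
    """Onset of discriminability between two trial ensembles.

    Computes the per-sample AUC for discriminating ``a`` from ``b``
    (direction-agnostic: an AUC of 0.2 discriminates as well as 0.8) and
    returns the first time it exceeds the threshold for the required
    persistence, or ``None`` if the ensembles never become discriminable.

    In differential mode the per-trial paired difference ``a - b`` is
    compared, sample by sample, against the pooled distribution of that
    difference in the pre-perturbation baseline window.
    """
    if a.t.shape != b.t.shape or not np.allclose(a.t, b.t):
        raise ValueError("ensembles must share the time grid")
    if a.n_trials < 5 or b.n_trials < 5:
        raise ValueError("need >= 5 trials per ensemble")
    if params.differential:
        if a.n_trials != b.n_trials:
            raise ValueError("differential mode requires paired ensembles")
        d = a.data - b.data
        w0, w1 = params.baseline_window
        base_mask = (a.t >= w0) & (a.t < w1)
        if not base_mask.any():
            raise ValueError("baseline window lies outside the time grid")
        baseline = d[:, base_mask].ravel()
        auc = _auc_columns(np.broadcast_to(baseline[:, None],
                                           (baseline.size, d.shape[1])), d)
    else:
        auc = _auc_columns(a.data, b.data)
    effect = np.maximum(auc, 1.0 - auc)
    n_persist = max(1, int(round(params.persistence_s * a.fs)))
    above = effect > params.threshold
    # first index opening a run of n_persist consecutive True values
    if above.any() and n_persist > 1:
        run = np.convolve(above.astype(int), np.ones(n_persist, int),
                          mode="valid")
        hits = np.flatnonzero(run == n_persist)
    else:
        hits = np.flatnonzero(above)
    onset = float(a.t[hits[0]]) if hits.size else None
    return RocResult(onset=onset, auc=auc, t=a.t)


# ---------------------------------------------------------------------------
# epoch statistics

def epoch_means(ens: TrialEnsemble,
                windows: dict[str, tuple[float, float]] | None = None,
                ) -> pd.DataFrame:
    """Per-trial mean activity in each epoch (half-open [start, end))."""
    windows = EPOCHS if windows is None else windows
    out = {}
    for name, (w0, w1) in windows.items():
        mask = (ens.t >= w0) & (ens.t < w1)
        if not mask.any():
            raise ValueError(f"epoch {name!r} [{w0}, {w1}) is outside the grid")
        out[name] = ens.data[:, mask].mean(axis=1)
    return pd.DataFrame(out)


def epoch_stats(a: TrialEnsemble, b: TrialEnsemble,
                windows: dict[str, tuple[float, float]] | None = None,
                alternative: str = "greater") -> pd.DataFrame:
    """Epoch means and one-tailed paired comparison of two ensembles.

    Trials are paired by index (equal trial counts required).  For each
    epoch the table reports the mean over trials in each ensemble and the
    paired one-tailed t statistic and p-value for ``a`` versus ``b``
    (``alternative='greater'`` tests a > b).  A pair of identical
    ensembles yields t = 0, p = 0.5.
    """
    if a.n_trials != b.n_trials:
        raise ValueError("paired ensembles must have equal trial counts")
    if a.n_trials < 2:
        raise ValueError("need at least 2 trial pairs")
    ma = epoch_means(a, windows)
    mb = epoch_means(b, windows)
    rows = []
    for name in ma.columns:
        diff = ma[name].to_numpy() - mb[name].to_numpy()
        if np.allclose(diff, 0.0):
            t_stat, p = 0.0, 0.5
        else:
            t_stat, p = stats.ttest_rel(ma[name], mb[name],
                                        alternative=alternative)
        rows.append({"epoch": name, "mean_a": ma[name].mean(),
                     "mean_b": mb[name].mean(), "t": float(t_stat),
                     "p": float(p), "n_pairs": a.n_trials,
                     "window": "half-open [start, end)"})
    return pd.DataFrame(rows)


def joint_speed_minimum(trace: SimulationTrace, window: float = 0.5,
                        onset: float | None = None) -> float | None:
    """Time of the first minimum of joint speed after the evoked peak.

    The Cartesian hand-speed minimum used for real limbs reduces, for a
    one-link geometry, to a minimum of the joint speed; this measure is
    provided under that reading.  Returns seconds relative to onset, or
    ``None`` when the speed never turns back up within the window.
    """
    t0 = _onset(trace, onset)
    speed = np.abs(trace.theta_dot)
    mask = (trace.t >= t0) & (trace.t <= t0 + window)
    idx = np.flatnonzero(mask)
    s = speed[idx]
    k_peak = int(np.argmax(s))
    mins, _ = signal.find_peaks(-s[k_peak:])
    if mins.size == 0:
        return None
    return float(trace.t[idx[k_peak + mins[0]]] - t0)
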