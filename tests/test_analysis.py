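import numpy as np
import pytest

from conftest import make_trace
from delaylqg.analysis import (
    EPOCHS,
    RocParams,
    TrialEnsemble,
    classify_stability,
    epoch_stats,
    estimation_error,
    joint_speed_minimum,
    reversal_time,
    roc_divergence_onset,
    settling_time,
)
from delaylqg.simulate import TrialConfig, make_profile, null_profile, run_trial
from delaylqg.synth_emg import EmgSpec, diverging_pair, generate_ensemble


def _parabola_trace():
    t = np.arange(0.0, 1.0001, 0.01)
    return make_trace(t, 4 * t * (1 - t), t_e=np.where(t > 0, 1.0, 0.0))


class TestReversalTime:
    def test_parabolic_displacement_peaks_at_half_second(self):
        tr = _parabola_trace()
        assert reversal_time(tr, window=1.0, onset=0.0) == pytest.approx(0.5)

    def test_amplitude_scaling_invariance(self):
        t = np.arange(0.0, 1.0001, 0.01)
        te = np.where(t > 0, 1.0, 0.0)
        t1 = make_trace(t, 4 * t * (1 - t), t_e=te)
        t2 = make_trace(t, 12 * t * (1 - t), t_e=te)
        assert reversal_time(t1, window=1.0, onset=0.0) == \
            reversal_time(t2, window=1.0, onset=0.0)

    def test_monotone_displacement_reports_no_reversal(self):
        t = np.arange(0.0, 0.6, 0.01)
        tr = make_trace(t, t ** 2, t_e=np.where(t > 0, 1.0, 0.0))
        assert reversal_time(tr, onset=0.0) is None

    def test_tie_breaks_to_earliest_sample(self):
        t = np.arange(0.0, 0.3, 0.01)
        disp = np.minimum(t * 10, 1.0)  # plateau from 0.1 s on
        tr = make_trace(t, disp, t_e=np.where(t > 0, 1.0, 0.0))
        assert reversal_time(tr, onset=0.0) == pytest.approx(0.1)

    def test_step_magnitude_invariance_of_model_responses(self):
        """The linear closed loop predicts one reversal time for every
        step amplitude."""
        times = []
        for mag in (1.0, 2.0, 3.0):
            cfg = TrialConfig(profile=make_profile("step", mag),
                              duration=1.5, noise_on=False)
            times.append(reversal_time(run_trial(cfg)))
        assert times[0] == times[1] == times[2]

    def test_catch_condition_ordering(self):
        """Ramp-down responses reverse earlier and ramp-up later than
        step responses under delay-aware estimation."""
        revs = {}
        for kind in ("step", "ramp_down", "ramp_up"):
            cfg = TrialConfig(profile=make_profile(kind, 2.0), duration=1.5,
                              noise_on=False)
            revs[kind] = reversal_time(run_trial(cfg))
        assert revs["ramp_down"] < revs["step"] < revs["ramp_up"]

    def test_reference_shifts_result(self):
        tr = _parabola_trace()
        assert reversal_time(tr, window=1.0, onset=0.0, reference=0.5) == \
            pytest.approx(0.0)

    def test_unperturbed_trace_needs_explicit_onset(self):
        cfg = TrialConfig(profile=null_profile(), duration=1.0,
                          noise_on=False)
        with pytest.raises(ValueError, match="onset"):
            reversal_time(run_trial(cfg))


class TestEstimationError:
    def test_unperturbed_noise_free_errors_identically_zero(self):
        cfg = TrialConfig(profile=null_profile(), duration=1.0,
                          noise_on=False)
        err = estimation_error(run_trial(cfg))
        assert np.allclose(err[["theta_err", "theta_dot_err", "T_E_err"]],
                           0.0, atol=1e-12)

    def test_step_torque_error_transient_decays(self):
        """The T_E estimation error spikes at the step and decays toward
        zero within about two feedback delays of the onset."""
        cfg = TrialConfig(profile=make_profile("step", 2.0), duration=1.0,
                          noise_on=False)
        tr = run_trial(cfg)
        err = estimation_error(tr)["T_E_err"].to_numpy()
        t0 = tr.effective_onset
        peak = np.max(np.abs(err))
        assert peak == pytest.approx(2.0, rel=0.01)  # full torque unseen
        late = tr.t >= t0 + 2 * 0.06 + 0.05
        assert np.max(np.abs(err[late])) < 0.05 * peak


class TestClassifyStability:
    def test_decaying_response_is_stable(self):
        t = np.arange(0.0, 4.0, 0.01)
        disp = np.deg2rad(8.0) * np.exp(-3 * t) * np.cos(8 * t)
        res = classify_stability(make_trace(t, disp))
        assert res.stable
        assert res.peak_trend < 1.0

    def test_growing_oscillation_is_unstable(self):
        t = np.arange(0.0, 4.0, 0.01)
        disp = np.deg2rad(0.5) * np.exp(0.8 * t) * np.cos(8 * t)
        res = classify_stability(make_trace(t, disp))
        assert not res.stable
        assert res.peak_trend > 1.0
        assert res.zero_crossings > 5

    def test_aborted_trace_is_unstable_regardless_of_duration(self):
        t = np.arange(0.0, 0.5, 0.01)
        res = classify_stability(make_trace(t, t * 10, abort_step=50))
        assert not res.stable and res.aborted

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 1.0, 0.01)
        with pytest.raises(ValueError, match="3 s"):
            classify_stability(make_trace(t, np.zeros_like(t)))

    def test_naive_step_response_classified_unstable(self):
        cfg = TrialConfig(profile=make_profile("step", 2.0),
                          condition="naive", duration=3.0, noise_on=False)
        assert not classify_stability(run_trial(cfg)).stable


class TestRocDivergence:
    def test_identical_ensembles_no_onset(self):
        rng = np.random.default_rng(0)
        t = np.arange(-0.05, 0.2, 0.001)
        a = TrialEnsemble(t=t, data=rng.normal(1, 0.1, (10, t.size)))
        b = TrialEnsemble(t=t, data=rng.normal(1, 0.1, (10, t.size)))
        res = roc_divergence_onset(a, b)
        assert res.onset is None
        assert abs(np.mean(res.auc) - 0.5) < 0.05

    def test_separation_after_60ms_detected_on_time(self):
        a, b = diverging_pair(EmgSpec(n_trials=20, seed=1), 0.060, snr=5.0)
        res = roc_divergence_onset(generate_ensemble(a),
                                   generate_ensemble(b))
        assert res.onset == pytest.approx(0.060, abs=0.005)

    def test_auc_invariant_under_monotone_transform(self):
        a, b = diverging_pair(EmgSpec(n_trials=12, seed=4), 0.080, snr=4.0)
        ea, eb = generate_ensemble(a), generate_ensemble(b)
        r1 = roc_divergence_onset(ea, eb)
        ea2 = TrialEnsemble(t=ea.t, data=np.exp(ea.data))
        eb2 = TrialEnsemble(t=eb.t, data=np.exp(eb.data))
        r2 = roc_divergence_onset(ea2, eb2)
        assert np.allclose(r1.auc, r2.auc)
        assert r1.onset == r2.onset

    def test_no_anticipation_of_the_divergence_time(self):
        """Ensembles sharing a generator until T never produce an onset
        earlier than one sample before T, across 100 seeds."""
        t_div = 0.060
        for s in range(100):
            a, b = diverging_pair(EmgSpec(n_trials=20, seed=2 * s), t_div,
                                  snr=4.0, seed_b=2 * s + 1)
            res = roc_divergence_onset(generate_ensemble(a),
                                       generate_ensemble(b))
            if res.onset is not None:
                assert res.onset >= t_div - 0.001

    def test_weaker_separation_never_detected_earlier(self):
        """Decreasing the separation/noise ratio can only delay (or lose)
        the detected onset."""
        onsets = []
        for snr in (6.0, 3.0, 1.5):
            errs = []
            for s in range(10):
                a, b = diverging_pair(EmgSpec(n_trials=15, seed=500 + 2 * s),
                                      0.060, snr=snr, seed_b=501 + 2 * s)
                r = roc_divergence_onset(generate_ensemble(a),
                                         generate_ensemble(b))
                errs.append(np.inf if r.onset is None else r.onset)
            onsets.append(np.median(errs))
        assert onsets[0] <= onsets[1] <= onsets[2]

    def test_differential_mode_uses_baseline_distribution(self):
        a, b = diverging_pair(EmgSpec(n_trials=20, seed=9), 0.060, snr=5.0)
        res = roc_divergence_onset(
            generate_ensemble(a), generate_ensemble(b),
            RocParams(differential=True))
        assert res.onset is not None
        assert res.onset == pytest.approx(0.060, abs=0.010)

    def test_mismatched_grids_rejected(self):
        t1 = np.arange(0.0, 0.1, 0.001)
        t2 = np.arange(0.0, 0.2, 0.001)
        a = TrialEnsemble(t=t1, data=np.ones((6, t1.size)))
        b = TrialEnsemble(t=t2, data=np.ones((6, t2.size)))
        with pytest.raises(ValueError, match="time grid"):
            roc_divergence_onset(a, b)

    def test_too_few_trials_rejected(self):
        t = np.arange(0.0, 0.1, 0.001)
        a = TrialEnsemble(t=t, data=np.ones((3, t.size)))
        b = TrialEnsemble(t=t, data=np.ones((6, t.size)))
        with pytest.raises(ValueError, match="trials"):
            roc_divergence_onset(a, b)

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            RocParams(threshold=0.4)
        with pytest.raises(ValueError):
            RocParams(persistence_s=0.0)


class TestEpochStats:
    def test_constant_signal_gives_zero_t(self):
        t = np.arange(-0.06, 0.2, 0.001)
        a = TrialEnsemble(t=t, data=np.full((6, t.size), 2.0))
        b = TrialEnsemble(t=t, data=np.full((6, t.size), 2.0))
        table = epoch_stats(a, b)
        assert (table["t"] == 0.0).all()
        assert (table["p"] == 0.5).all()
        assert (table["mean_a"] == table["mean_b"]).all()

    def test_epoch_boundaries_half_open(self):
        """A burst exactly at 45 ms belongs to R2, not R1."""
        t = np.arange(-0.06, 0.2, 0.001)
        data = np.zeros((6, t.size))
        data[:, np.isclose(t, 0.045)] = 100.0 + np.arange(6)[:, None]
        a = TrialEnsemble(t=t, data=data)
        b = TrialEnsemble(t=t, data=np.zeros_like(data))
        table = epoch_stats(a, b).set_index("epoch")
        assert table.loc["r1", "mean_a"] == 0.0
        assert table.loc["r2", "mean_a"] > 0.0

    def test_paired_t_matches_hand_computation(self):
        """Four pairs with differences (1, 2, 3, 2):
        t = 2 / (sqrt(2/3)/2) = 4.898979, one-tailed p = 0.008138."""
        t = np.arange(-0.06, 0.2, 0.001)
        base = np.zeros((4, t.size))
        diffs = np.array([1.0, 2.0, 3.0, 2.0])
        a = TrialEnsemble(t=t, data=base + diffs[:, None])
        b = TrialEnsemble(t=t, data=base)
        table = epoch_stats(a, b).set_index("epoch")
        assert table.loc["r2", "t"] == pytest.approx(4.898979, abs=1e-5)
        assert table.loc["r2", "p"] == pytest.approx(0.008138, abs=1e-5)

    def test_epoch_windows_match_classical_definitions(self):
        assert EPOCHS["pre"] == (-0.050, 0.0)
        assert EPOCHS["r1"] == (0.020, 0.045)
        assert EPOCHS["r2"] == (0.045, 0.075)
        assert EPOCHS["r3"] == (0.075, 0.105)
        assert EPOCHS["voluntary"] == (0.120, 0.180)

    def test_unequal_trial_counts_rejected(self):
        t = np.arange(-0.06, 0.2, 0.001)
        a = TrialEnsemble(t=t, data=np.ones((5, t.size)))
        b = TrialEnsemble(t=t, data=np.ones((6, t.size)))
        with pytest.raises(ValueError, match="equal trial counts"):
            epoch_stats(a, b)

    def test_single_pair_rejected(self):
        t = np.arange(-0.06, 0.2, 0.001)
        a = TrialEnsemble(t=t, data=np.ones((1, t.size)))
        with pytest.raises(ValueError, match="2 trial pairs"):
            epoch_stats(a, a)


class TestAuxiliaryMeasures:
    def test_settling_time_simple_decay(self):
        # 10 deg excursion held until 1 s, back inside 1 deg afterwards
        t = np.arange(0.0, 2.0, 0.01)
        disp = np.where(t < 1.0, np.deg2rad(10.0), 0.0)
        disp[0] = 0.0
        tr = make_trace(t, disp, t_e=np.where(t > 0, 1.0, 0.0))
        assert settling_time(tr, onset=0.0) == pytest.approx(1.0)
        # a displacement that never returns has no settling time
        tr2 = make_trace(t, np.minimum(2 * t, 1.0) * np.deg2rad(10.0),
                         t_e=np.where(t > 0, 1.0, 0.0))
        assert settling_time(tr2, onset=0.0) is None

    def test_joint_speed_minimum_follows_the_speed_peak(self):
        cfg = TrialConfig(profile=make_profile("step", 2.0), duration=1.5,
                          noise_on=False)
        tr = run_trial(cfg)
        tmin = joint_speed_minimum(tr)
        assert tmin is not None
        assert 0.0 < tmin < 0.5

    def test_ensemble_csv_round_trip(self, tmp_path):
        ens = generate_ensemble(EmgSpec(n_trials=5, seed=2))
        path = tmp_path / "ens.csv"
        ens.to_csv(path)
        back = TrialEnsemble.from_csv(path)
        assert np.allclose(back.t, ens.t)
        assert np.allclose(back.data, ens.data)
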