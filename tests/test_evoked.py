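"""Trial averaging, evoked summaries, HbR waveform class, gas challenge."""

import numpy as np
import pytest

from oispec import (
    HaemSeries,
    TrialSet,
    classify_hbr,
    gas_challenge_response,
    summarise_evoked,
    trial_average,
)


def _roi_series(hbt, frame_rate=5.0):
    hbt = np.asarray(hbt, dtype=float)
    return HaemSeries(hbt=hbt, hbo=hbt.copy(), hbr=hbt.copy(),
                      frame_rate=frame_rate, mode="fractional")


def _kernel_trace(times, onset, peak=0.05, tp=3.0):
    """Compact-support response bump (exactly zero outside (0, 4*tp)) so
    neighbouring trials never overlap."""
    t = times - onset
    inside = (t > 0) & (t < 4 * tp)
    k = np.where(inside, np.sin(np.pi * np.clip(t, 0, 4 * tp) / (4 * tp)) ** 2, 0.0)
    return 1.0 + peak * k


class TestTrialAverage:
    def _make(self, n_trials=5, noise=0.0, seed=0, fr=5.0):
        rng = np.random.default_rng(seed)
        onsets = 10.0 + 25.0 * np.arange(n_trials)
        duration = onsets[-1] + 25.0
        t = np.arange(int(duration * fr)) / fr
        hbt = np.ones_like(t)
        for o in onsets:
            hbt += _kernel_trace(t, o) - 1.0
        hbt = hbt + noise * rng.standard_normal(t.size)
        trials = TrialSet(onsets=tuple(onsets), stim_duration=2.0,
                          pre_window=4.0, post_window=20.0)
        return _roi_series(hbt, fr), trials, t

    def test_identical_trials_mean_equals_single_trial_sem_zero(self):
        series, trials, _ = self._make(n_trials=4)
        tr = trial_average(series, trials)
        single = trial_average(series, TrialSet(onsets=(trials.onsets[0],),
                                                stim_duration=2.0, pre_window=4.0,
                                                post_window=20.0))
        assert np.allclose(tr.hbt, single.hbt, atol=1e-12)
        assert np.allclose(tr.sem_hbt, 0.0, atol=1e-12)

    def test_single_trial_reports_absent_sem(self):
        series, trials, _ = self._make(n_trials=1)
        tr = trial_average(series, trials)
        assert tr.sem_hbt is None

    def test_sem_shrinks_as_sqrt_n(self):
        _, _, _ = self._make()
        sems = {}
        for n in (8, 32):
            series, trials, _ = self._make(n_trials=n, noise=0.01, seed=3)
            tr = trial_average(series, trials)
            sems[n] = tr.sem_hbt.mean()
        assert sems[32] / sems[8] == pytest.approx(0.5, rel=0.35)

    def test_mean_converges_to_kernel(self):
        series, trials, _ = self._make(n_trials=40, noise=0.01, seed=5)
        tr = trial_average(series, trials)
        expected = _kernel_trace(tr.times, 0.0)
        assert np.abs(tr.hbt - expected).max() < 4 * 0.01 / np.sqrt(40) * 3

    def test_rebaselining_centres_pre_window_at_unity(self):
        series, trials, _ = self._make(n_trials=10, noise=0.02, seed=7)
        tr = trial_average(series, trials)
        pre = tr.hbt[tr.times < 0]
        assert pre.mean() == pytest.approx(1.0, abs=3 * 0.02 / np.sqrt(10 * pre.size))

    def test_trial_beyond_recording_rejected(self):
        series, _, _ = self._make(n_trials=2)
        bad = TrialSet(onsets=(10.0, 10000.0), stim_duration=2.0,
                       pre_window=4.0, post_window=20.0)
        with pytest.raises(ValueError, match="trial 1"):
            trial_average(series, bad)

    def test_overlapping_trials_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TrialSet(onsets=(10.0, 15.0), stim_duration=2.0,
                     pre_window=4.0, post_window=20.0)


class TestSummariseEvoked:
    def test_triangular_pulse_metrics(self):
        fr = 50.0
        times = np.arange(-2 * fr, 10 * fr) / fr
        trace = np.ones_like(times)
        rise = (times >= 0) & (times <= 2.0)
        fall = (times > 2.0) & (times <= 4.0)
        trace[rise] = 1.0 + 0.05 * times[rise] / 2.0
        trace[fall] = 1.0 + 0.05 * (4.0 - times[fall]) / 2.0
        s = summarise_evoked(times, trace, stim_duration=2.0)
        assert s.peak == pytest.approx(0.05, abs=1e-12)
        assert s.time_to_peak == pytest.approx(2.0, abs=1 / fr)
        # linear rise: 10% -> 90% spans 80% of the 2 s rise
        assert s.rise_time == pytest.approx(1.6, abs=2 / fr)
        # triangle area = 0.5 * base * height
        assert s.auc == pytest.approx(0.5 * 4.0 * 0.05, rel=0.01)

    def test_flat_trace_reports_zero_peak_absent_times(self):
        times = np.arange(-10, 50) / 5.0
        s = summarise_evoked(times, np.ones_like(times), stim_duration=2.0)
        assert s.peak == 0.0 and s.time_to_peak is None and s.auc == 0.0

    def test_signed_extremum_for_washout(self):
        times = np.arange(-10, 100) / 5.0
        trace = 1.0 - 0.03 * np.exp(-((times - 4.0) / 2.0) ** 2)
        s = summarise_evoked(times, trace, stim_duration=2.0, signed=True)
        assert s.peak == pytest.approx(-0.03, abs=1e-6)
        assert s.time_to_peak == pytest.approx(4.0, abs=0.2)

    def test_rise_time_never_exceeds_time_to_peak(self, rng):
        times = np.arange(-20, 100) / 5.0
        for _ in range(20):
            trace = 1.0 + 0.05 * np.clip(rng.standard_normal(times.size).cumsum() / 30, 0, None)
            s = summarise_evoked(times, trace, stim_duration=2.0)
            if s.rise_time is not None:
                assert s.rise_time <= s.time_to_peak + 1e-9


class TestClassifyHbr:
    times = np.arange(-20, 100) / 5.0

    def _washout(self, bump=0.0):
        t = self.times
        trace = 1.0 - 0.04 * np.exp(-((t - 5.0) / 2.5) ** 2)
        trace += bump * np.exp(-((t - 1.5) / 1.0) ** 2)
        return trace

    def test_clean_shapes(self):
        assert classify_hbr(self.times, self._washout(), noise_floor=0.005) == "biphasic"
        assert classify_hbr(self.times, self._washout(bump=0.02), noise_floor=0.005) == "triphasic"
        assert classify_hbr(self.times, np.ones_like(self.times), noise_floor=0.005) == "flat"

    def test_pure_noise_labelled_flat_in_95pct_of_draws(self):
        n_flat = 0
        n_seeds = 60
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            trace = 1.0 + 0.003 * rng.standard_normal(self.times.size)
            n_flat += classify_hbr(self.times, trace) == "flat"
        assert n_flat / n_seeds >= 0.95


class TestGasChallenge:
    def test_step_response_mean_and_auc(self):
        fr = 5.0
        t = np.arange(0, 200 * 5) / fr
        hbt = np.ones_like(t)
        hbt[(t >= 60.0) & (t < 120.0)] = 1.2
        mean, auc = gas_challenge_response(_roi_series(hbt), (60.0, 120.0), (0.0, 60.0))
        assert mean == pytest.approx(0.2, abs=1e-9)
        assert auc == pytest.approx(0.2 * 60.0, rel=0.02)

    def test_flat_series_gives_zero(self):
        t = np.arange(0, 500) / 5.0
        mean, auc = gas_challenge_response(_roi_series(np.ones_like(t)), (40.0, 80.0), (0.0, 40.0))
        assert mean == 0.0 and auc == 0.0

    def test_ramp_auc_matches_closed_form_integral(self):
        fr = 10.0
        t = np.arange(0, 100 * 10) / fr
        hbt = np.ones_like(t)
        win = (t >= 20.0) & (t < 80.0)
        hbt[win] = 1.0 + 0.3 * (t[win] - 20.0) / 60.0  # linear ramp 0 -> 0.3
        mean, auc = gas_challenge_response(_roi_series(hbt, fr), (20.0, 80.0), (0.0, 20.0))
        assert auc == pytest.approx(0.5 * 0.3 * 60.0, rel=0.02)

    def test_window_outside_recording_rejected(self):
        t = np.arange(0, 100) / 5.0
        with pytest.raises(ValueError):
            gas_challenge_response(_roi_series(np.ones_like(t)), (500.0, 600.0), (0.0, 10.0))
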