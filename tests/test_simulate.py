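"""Forward simulator: evoked fields, CSD waves, rendering, electrophysiology."""

import numpy as np
import pytest

from oispec import (
    CSDParams,
    EvokedKernelParams,
    NeuralSimParams,
    SimConfig,
    compute_attenuation,
    disc_mask,
    render_reflectance,
    simulate_csd_field,
    simulate_electrode,
    simulate_evoked_field,
)


def _small_cfg(**kw):
    defaults = dict(grid=(8, 8), duration=40.0, noise_sigma=0.0, seed=1)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestEvokedField:
    def test_null_response_stays_at_baseline(self):
        cfg = _small_cfg()
        kp = EvokedKernelParams(peak_fraction=0.0)
        mask = disc_mask(cfg.grid, (4, 4), 2)
        h = simulate_evoked_field(cfg, kp, mask, [10.0]).to_fractional()
        assert np.all(h.hbt == 1.0) and np.all(h.hbo == 1.0) and np.all(h.hbr == 1.0)

    def test_peak_amplitude_and_timing(self):
        cfg = _small_cfg()
        kp = EvokedKernelParams(peak_fraction=0.05, time_to_peak=3.0, onset_delay=0.0)
        mask = disc_mask(cfg.grid, (4, 4), 2)
        h = simulate_evoked_field(cfg, kp, mask, [10.0]).to_fractional()
        px = h.hbt[:, 4, 4]
        assert px.max() == pytest.approx(1.05, abs=1e-9)
        assert h.times[np.argmax(px)] == pytest.approx(13.0, abs=1e-9)
        assert np.all(h.hbt[:, 0, 0] == 1.0)  # outside the active region

    def test_triphasic_hbr_crosses_baseline_at_least_twice(self):
        cfg = _small_cfg()
        kp = EvokedKernelParams(hbr_mode="triphasic", triphasic_bump_fraction=0.02)
        mask = disc_mask(cfg.grid, (4, 4), 2)
        h = simulate_evoked_field(cfg, kp, mask, [10.0]).to_fractional()
        hbr = h.hbr[:, 4, 4]
        dev = hbr - 1.0
        active = dev[np.abs(dev) > 1e-9]
        crossings = np.sum(np.diff(np.sign(active)) != 0)
        assert crossings >= 2
        assert hbr.max() > 1.0 and hbr.min() < 1.0

    def test_conservation_in_absolute_mode(self):
        cfg = _small_cfg()
        kp = EvokedKernelParams(hbr_mode="triphasic", triphasic_bump_fraction=0.02)
        mask = disc_mask(cfg.grid, (4, 4), 2)
        h = simulate_evoked_field(cfg, kp, mask, [10.0])
        assert np.allclose(h.hbt, h.hbo + h.hbr, atol=1e-12)

    def test_overlapping_stimuli_rejected(self):
        cfg = _small_cfg()
        kp = EvokedKernelParams(stimulus_duration=2.0)
        mask = disc_mask(cfg.grid, (4, 4), 2)
        with pytest.raises(ValueError, match="overlap"):
            simulate_evoked_field(cfg, kp, mask, [10.0, 11.0])


class TestCSDField:
    def test_infinite_speed_limit_is_synchronous(self):
        cfg = _small_cfg(grid=(8, 8), duration=200.0, frame_rate=1.0)
        csd = CSDParams(origin=(0, 0), speed_mm_per_min=1e9)
        h = simulate_csd_field(cfg, csd).to_fractional()
        assert np.allclose(h.hbt[:, 0, 0], h.hbt[:, 7, 7], atol=1e-9)

    def test_propagation_delay_separates_profiles(self):
        # two pixels 1 mm apart at 3 mm/min arrive 20 s apart
        cfg = SimConfig(grid=(1, 2), pixel_pitch_um=1000.0, frame_rate=5.0,
                        duration=120.0, noise_sigma=0.0, seed=0)
        csd = CSDParams(origin=(0, 0), speed_mm_per_min=3.0)
        h = simulate_csd_field(cfg, csd).to_fractional()
        t = h.times
        t_min0 = t[np.argmin(h.hbt[:, 0, 0])]
        t_min1 = t[np.argmin(h.hbt[:, 0, 1])]
        assert t_min1 - t_min0 == pytest.approx(20.0, abs=1.0 / cfg.frame_rate)

    def test_fast_undershoot_decay_recovers_late_window(self):
        cfg = _small_cfg(grid=(2, 2), duration=700.0, frame_rate=1.0)
        csd = CSDParams(origin=(0, 0), undershoot_decay_tau=20.0)
        h = simulate_csd_field(cfg, csd).to_fractional()
        late = h.hbt[h.times >= 500.0]
        assert np.abs(late.mean() - 1.0) < 1e-3

    def test_dip_depth_matches_configuration(self):
        cfg = _small_cfg(grid=(2, 2), duration=200.0, frame_rate=5.0)
        csd = CSDParams(origin=(0, 0), dip_fraction=0.70)
        h = simulate_csd_field(cfg, csd).to_fractional()
        assert h.hbt[:, 0, 0].min() == pytest.approx(0.70, abs=0.02)


class TestRenderReflectance:
    def test_zero_change_zero_noise_gives_flat_stack(self, spectra):
        cfg = _small_cfg()
        kp = EvokedKernelParams(peak_fraction=0.0)
        truth = simulate_evoked_field(cfg, kp, disc_mask(cfg.grid, (4, 4), 2), [10.0])
        stack = render_reflectance(truth, spectra, cfg=cfg)
        assert np.all(stack.frames == 1.0)

    def test_roundtrip_attenuation_identity(self, spectra):
        """compute_attenuation(render(truth)) equals the Beer-Lambert
        attenuation of the truth field to machine precision."""
        cfg = _small_cfg()
        kp = EvokedKernelParams(peak_fraction=0.05)
        truth = simulate_evoked_field(cfg, kp, disc_mask(cfg.grid, (4, 4), 2), [10.0])
        stack = render_reflectance(truth, spectra, cfg=cfg)
        att = compute_attenuation(stack, (0.0, 4.0))
        S = truth.saturation()
        L = spectra.pathlength(S)
        expected = L * (spectra.eps_hbo * truth.hbo[..., None] * 1e-6
                        + spectra.eps_hbr * truth.hbr[..., None] * 1e-6)
        assert np.abs(att.values - expected).max() < 1e-10

    def test_fixed_seed_is_bit_identical(self, spectra):
        cfg = _small_cfg(noise_sigma=0.02, seed=42)
        kp = EvokedKernelParams()
        truth = simulate_evoked_field(cfg, kp, disc_mask(cfg.grid, (4, 4), 2), [10.0])
        s1 = render_reflectance(truth, spectra, cfg=cfg)
        s2 = render_reflectance(truth, spectra, cfg=cfg)
        assert np.array_equal(s1.frames, s2.frames)

    def test_fractional_truth_rejected(self, spectra):
        cfg = _small_cfg()
        kp = EvokedKernelParams()
        truth = simulate_evoked_field(cfg, kp, disc_mask(cfg.grid, (4, 4), 2), [10.0])
        with pytest.raises(ValueError, match="absolute"):
            render_reflectance(truth.to_fractional(), spectra, cfg=cfg)


class TestElectrode:
    def test_fixed_seed_is_bit_identical(self):
        p = NeuralSimParams(n_channels=2, sampling_rate=10000.0)
        r1, e1 = simulate_electrode(5.0, p, [2.0], 1.0, seed=7)
        r2, e2 = simulate_electrode(5.0, p, [2.0], 1.0, seed=7)
        assert np.array_equal(r1.traces, r2.traces)
        assert all(np.array_equal(a, b) for a, b in zip(e1, e2))

    def test_unity_gain_does_not_modulate_rate(self):
        """With evoked_gain = 1 the ground-truth event counts in stimulus and
        matched baseline windows agree within Poisson error (>=100 trials)."""
        p = NeuralSimParams(n_channels=1, sampling_rate=10000.0, evoked_gain=1.0)
        stim_n = base_n = 0
        n_trials = 120
        for s in range(n_trials):
            _, ev = simulate_electrode(6.0, p, [3.0], 2.0, seed=100 + s)
            t = ev[0]
            stim_n += np.sum((t >= 3.0) & (t < 5.0))
            base_n += np.sum((t >= 0.0) & (t < 2.0))
        total = stim_n + base_n
        # difference of two Poisson counts with equal mean
        assert abs(stim_n - base_n) < 4 * np.sqrt(total)

    def test_poisson_mean_during_stimulus(self):
        """baseline 10/s, gain 2, 2 s stimulus: 40 expected events/channel."""
        p = NeuralSimParams(n_channels=4, sampling_rate=10000.0,
                            baseline_rate=10.0, evoked_gain=2.0)
        counts = []
        for s in range(40):
            _, ev = simulate_electrode(6.0, p, [3.0], 2.0, seed=500 + s)
            counts += [np.sum((t >= 3.0) & (t < 5.0)) for t in ev]
        counts = np.asarray(counts, dtype=float)
        sem = counts.std(ddof=1) / np.sqrt(counts.size)
        assert counts.mean() == pytest.approx(40.0, abs=4 * sem)

    def test_undersampled_rate_rejected(self):
        p = NeuralSimParams(sampling_rate=2000.0)
        with pytest.raises(ValueError, match="below twice"):
            simulate_electrode(2.0, p, [1.0], 0.5, seed=0)
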