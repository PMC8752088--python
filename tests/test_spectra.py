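"""Spectral conversion: attenuation, Beer-Lambert inversion, PLSA."""

import numpy as np
import pytest

from oispec import (
    AttenuationSeries,
    BaselineState,
    ReflectanceStack,
    compute_attenuation,
    default_spectra,
    plsa_refine,
    unmix,
)
from oispec.spectra import SpectraTables, load_extinction_tsv, load_pathlength_tsv, write_pathlength_tsv


def _flat_stack(value=1.0, T=10, H=3, W=3, L=4):
    lam = (494.0, 560.0, 575.0, 595.0)[:L]
    return ReflectanceStack(np.full((T, H, W, L), value), lam, frame_rate=5.0)


def _forward_atten(spectra, baseline, dc_hbo_uM, dc_hbr_uM, saturation=None):
    """Independent forward model: dA = L(S) * (eps_o*dc_o + eps_r*dc_r)."""
    s = baseline.s0 if saturation is None else saturation
    L = spectra.pathlength(s)
    return L * (spectra.eps_hbo * dc_hbo_uM[..., None] * 1e-6
                + spectra.eps_hbr * dc_hbr_uM[..., None] * 1e-6)


class TestComputeAttenuation:
    def test_baseline_frames_give_zero(self):
        att = compute_attenuation(_flat_stack(), (0.0, 1.0))
        assert np.all(att.values == 0.0)

    def test_known_decrement_recovers_log_ratio(self):
        stack = _flat_stack()
        stack.frames[5, 1, 2, 0] = np.exp(-0.1)  # I = I0 * e^-0.1
        att = compute_attenuation(stack, (0.0, 0.5))
        assert att.values[5, 1, 2, 0] == pytest.approx(0.1, abs=1e-12)
        other = att.values.copy()
        other[5, 1, 2, 0] = 0.0
        assert np.all(other == 0.0)

    def test_nonpositive_intensity_rejected_with_frame_info(self):
        stack = _flat_stack()
        stack.frames[3, 0, 0, 1] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            compute_attenuation(stack, (0.0, 1.0))

    def test_short_baseline_window_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_attenuation(_flat_stack(), (0.0, 0.1))


class TestUnmix:
    def test_zero_attenuation_gives_unit_fractional(self, spectra, baseline):
        att = AttenuationSeries(np.zeros((5, 2, 2, 4)), spectra.wavelengths_nm, 5.0, (0, 1))
        h = unmix(att, spectra, baseline)
        assert np.all(h.hbt == 1.0) and np.all(h.hbo == 1.0) and np.all(h.hbr == 1.0)

    def test_forward_inverse_roundtrip_four_wavelengths(self, spectra, baseline, rng):
        dc_hbo = rng.normal(0, 5, (20, 4, 4))
        dc_hbr = rng.normal(0, 3, (20, 4, 4))
        dA = _forward_atten(spectra, baseline, dc_hbo, dc_hbr)
        att = AttenuationSeries(dA, spectra.wavelengths_nm, 5.0, (0, 1))
        h = unmix(att, spectra, baseline, output="absolute")
        scale = np.abs(dc_hbo).max()
        assert np.abs(h.hbo - dc_hbo).max() / scale < 1e-8
        assert np.abs(h.hbr - dc_hbr).max() / scale < 1e-8

    def test_noise_covariance_matches_least_squares_prediction(self, spectra, baseline, rng):
        """Monte-Carlo concentration scatter equals the closed-form
        (X^T X)^-1 sigma^2 covariance of the linear inversion."""
        sigma = 1e-3
        n = 20000
        L = spectra.pathlength(baseline.s0)
        X = np.column_stack([L * spectra.eps_hbo, L * spectra.eps_hbr])
        expected_cov = np.linalg.inv(X.T @ X) * sigma**2  # in M^2
        dA = rng.normal(0.0, sigma, (n, 1, 1, 4))
        att = AttenuationSeries(dA, spectra.wavelengths_nm, 5.0, (0, 1))
        h = unmix(att, spectra, baseline, output="absolute")
        est = np.cov(h.hbo[:, 0, 0] * 1e-6, h.hbr[:, 0, 0] * 1e-6)
        assert np.allclose(est, expected_cov, rtol=0.08)

    def test_rank_deficient_design_rejected(self, baseline):
        # one wavelength duplicated: the two chromophores are inseparable
        full = default_spectra((560.0, 560.0))
        att = AttenuationSeries(np.zeros((3, 1, 1, 2)), full.wavelengths_nm, 5.0, (0, 1))
        with pytest.raises(ValueError, match="condition number"):
            unmix(att, full, baseline)

    def test_linearity_doubling_attenuation_doubles_concentrations(self, spectra, baseline, rng):
        dA = rng.normal(0, 0.01, (6, 2, 2, 4))
        a1 = AttenuationSeries(dA, spectra.wavelengths_nm, 5.0, (0, 1))
        a2 = AttenuationSeries(2 * dA, spectra.wavelengths_nm, 5.0, (0, 1))
        h1 = unmix(a1, spectra, baseline, output="absolute")
        h2 = unmix(a2, spectra, baseline, output="absolute")
        assert np.allclose(h2.hbo, 2 * h1.hbo, rtol=0, atol=1e-12)
        assert np.allclose(h2.hbr, 2 * h1.hbr, rtol=0, atol=1e-12)

    def test_conservation_hbt_equals_hbo_plus_hbr(self, spectra, baseline, rng):
        dA = rng.normal(0, 0.02, (50, 3, 3, 4))
        att = AttenuationSeries(dA, spectra.wavelengths_nm, 5.0, (0, 1))
        for method in (unmix, plsa_refine):
            h = method(att, spectra, baseline, output="absolute")
            resid = np.abs(h.hbt - (h.hbo + h.hbr))
            assert resid.max() <= 1e-12 * max(np.abs(h.hbt).max(), 1.0)

    def test_fractional_output_invariant_to_baseline_rescale(self, spectra, rng):
        """Fractional changes do not depend on the assumed resting HbT when
        the underlying truth is itself fractional."""
        frac_dev_hbt = 0.05 * rng.random((10, 2, 2))
        results = []
        for c0 in (50.0, 100.0, 200.0):
            b = BaselineState(c_hbt0=c0, s0=0.70)
            dc_hbt = frac_dev_hbt * c0
            dc_hbo, dc_hbr = 1.3 * dc_hbt, -0.3 * dc_hbt
            dA = _forward_atten(spectra, b, dc_hbo, dc_hbr)
            att = AttenuationSeries(dA, spectra.wavelengths_nm, 5.0, (0, 1))
            results.append(unmix(att, spectra, b).hbt)
        assert np.allclose(results[0], results[1], atol=1e-10)
        assert np.allclose(results[1], results[2], atol=1e-10)


class TestPLSA:
    def _grid_tables(self, spectra, constant=True):
        sat = np.linspace(0.05, 1.0, 20)
        if constant:
            grid = np.tile(spectra.pathlength(0.7), (sat.size, 1))
        else:
            grid = np.stack([spectra.pathlength(float(s)) for s in sat])
        return SpectraTables(
            wavelengths_nm=spectra.wavelengths_nm,
            eps_hbo=spectra.eps_hbo,
            eps_hbr=spectra.eps_hbr,
            sat_grid=sat,
            pathlength_grid=grid,
        )

    def test_constant_pathlength_table_reduces_to_single_pass(self, spectra, baseline, rng):
        tables = self._grid_tables(spectra, constant=True)
        dA = rng.normal(0, 0.02, (8, 2, 2, 4))
        att = AttenuationSeries(dA, tables.wavelengths_nm, 5.0, (0, 1))
        h_plsa = plsa_refine(att, tables, baseline)
        h_once = unmix(att, tables, baseline)
        assert np.allclose(h_plsa.hbt, h_once.hbt, atol=1e-12)
        assert h_plsa.meta["converged"]

    def test_infinite_tolerance_returns_first_iterate(self, spectra, baseline, rng):
        dA = rng.normal(0, 0.02, (8, 2, 2, 4))
        att = AttenuationSeries(dA, spectra.wavelengths_nm, 5.0, (0, 1))
        h_plsa = plsa_refine(att, spectra, baseline, tol=np.inf)
        h_once = unmix(att, spectra, baseline)
        assert np.allclose(h_plsa.hbt, h_once.hbt, atol=1e-14)

    def test_plsa_beats_single_pass_under_desaturation(self, spectra, baseline):
        """A constriction that drops saturation 0.70 -> ~0.55 changes the
        pathlengths; PLSA tracks the change, single-pass unmixing cannot."""
        t = np.linspace(0, 1, 30)
        dc_hbt = -30.0 * np.sin(np.pi * t)[:, None, None] * np.ones((1, 2, 2))
        dc_hbo = 1.05 * dc_hbt
        dc_hbr = dc_hbt - dc_hbo
        S_true = (baseline.c_hbo0 + dc_hbo) / (baseline.c_hbt0 + dc_hbt)
        assert S_true.min() == pytest.approx(0.55, abs=0.02)
        L = spectra.pathlength(S_true)
        dA = L * (spectra.eps_hbo * dc_hbo[..., None] * 1e-6
                  + spectra.eps_hbr * dc_hbr[..., None] * 1e-6)
        att = AttenuationSeries(dA, spectra.wavelengths_nm, 5.0, (0, 1))
        scale = np.abs(dc_hbo).max()
        err_once = np.abs(unmix(att, spectra, baseline, output="absolute").hbo - dc_hbo).max() / scale
        h = plsa_refine(att, spectra, baseline, tol=1e-8, max_iter=50, output="absolute")
        err_plsa = np.abs(h.hbo - dc_hbo).max() / scale
        assert err_plsa < 0.02
        assert err_plsa < err_once
        assert h.meta["converged"]

    def test_saturation_clamp_flags_pixels(self, spectra, baseline):
        # absurd attenuation drives saturation out of (0, 1)
        dA = np.full((6, 1, 1, 4), 0.0)
        dA[3:] = [[-2.0, 1.5, 1.2, -1.8]]
        att = AttenuationSeries(dA, spectra.wavelengths_nm, 5.0, (0, 1))
        h = plsa_refine(att, spectra, baseline)
        assert h.meta["clamped_fraction"] > 0


class TestTables:
    def test_packaged_extinction_positive_and_dense(self):
        df = load_extinction_tsv()
        assert (df["eps_hbo"] > 0).all() and (df["eps_hbr"] > 0).all()
        assert df["wavelength_nm"].min() <= 450 and df["wavelength_nm"].max() >= 650
        assert np.diff(np.sort(df["wavelength_nm"])).max() <= 1.0

    def test_missing_instrument_wavelength_rejected(self):
        with pytest.raises(ValueError, match="no table entry"):
            default_spectra((700.0,))

    def test_pathlength_tsv_roundtrip(self, spectra, tmp_path):
        p = tmp_path / "pl.tsv"
        write_pathlength_tsv(p, spectra)
        loaded = load_pathlength_tsv(p)
        for s in (0.40, 0.70, 0.95):
            assert np.allclose(loaded.pathlength(s), spectra.pathlength(s), rtol=1e-3)

    def test_saturation_grid_must_span_range(self, spectra):
        with pytest.raises(ValueError, match="span"):
            SpectraTables(
                wavelengths_nm=spectra.wavelengths_nm,
                eps_hbo=spectra.eps_hbo,
                eps_hbr=spectra.eps_hbr,
                sat_grid=np.linspace(0.5, 1.0, 5),
                pathlength_grid=np.ones((5, 4)) * 0.04,
            )
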