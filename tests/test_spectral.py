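"""Tests of block spectra, normalization/compensation, regression features,
and the depth-slope local attenuation estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import refqus as rq
from refqus.spectral import (
    BlockSpectrum,
    LocalAttenuationResult,
    block_power_spectrum,
    estimate_local_attenuation,
    next_pow2,
)


class TestBlockPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        fs = 40.0
        t = np.arange(256) / fs
        block = np.sin(2 * np.pi * 6.0 * t)[:, None] * np.ones((1, 8))
        spec = block_power_spectrum(block, fs)
        f_peak = spec.freq_mhz[np.argmax(spec.power)]
        df = spec.freq_mhz[1] - spec.freq_mhz[0]
        assert abs(f_peak - 6.0) <= df

    def test_quadratic_amplitude_scaling(self, rng):
        block = rng.standard_normal((128, 8))
        a = block_power_spectrum(block, 40.0)
        b = block_power_spectrum(2.0 * block, 40.0)
        assert np.allclose(b.power, 4.0 * a.power)

    def test_white_noise_is_flat_on_average(self, rng):
        """Mean spectrum of white noise is flat within Monte-Carlo error."""
        block = rng.standard_normal((128, 400))
        spec = block_power_spectrum(block, 40.0)
        inner = spec.power[5:-5]  # avoid DC/Nyquist halving
        rel = inner / inner.mean()
        # per-bin averaging error ~ 1/sqrt(n_lines); allow 5 sigma
        assert np.max(np.abs(rel - 1.0)) < 5.0 / np.sqrt(400)

    def test_all_zero_block_floored_and_flagged(self):
        spec = block_power_spectrum(np.zeros((64, 4)), 40.0)
        assert spec.flagged
        assert np.all(spec.power == np.finfo(float).eps)

    def test_short_block_rejected(self):
        with pytest.raises(ValueError, match="16"):
            block_power_spectrum(np.zeros((8, 4)), 40.0)

    def test_zero_padding_to_four_times(self):
        spec = block_power_spectrum(np.zeros((100, 2)), 40.0)
        assert spec.freq_mhz.size == next_pow2(400) // 2 + 1


class TestCompensation:
    def test_closed_form_power_factor(self):
        """α_i = 1 dB/(MHz·cm), f = 6 MHz, z_i = 1 cm → ×15.85 (+12 dB)."""
        att = rq.AttenuationSet(alpha_tissue=1.0, alpha_local=0.0, alpha_ref=0.0)
        fac = rq.compensation_factor(np.array([6.0]), att, 1.0, 0.0, 1.0)
        assert fac[0] == pytest.approx(np.exp(4.0 * 6.0 / 8.6859))
        assert fac[0] == pytest.approx(15.85, abs=0.01)

    def test_zero_attenuation_is_pure_ratio(self, rng):
        freq = np.fft.rfftfreq(256, d=1 / 40.0)
        ws = BlockSpectrum(freq, rng.uniform(0.5, 2.0, freq.size))
        wr = BlockSpectrum(freq, rng.uniform(0.5, 2.0, freq.size))
        att = rq.AttenuationSet(alpha_tissue=0.0, alpha_local=0.0, alpha_ref=0.0)
        nps = rq.normalize_and_compensate(ws, wr, att, 0.5, 0.5, 1.0, (3.0, 8.0))
        keep = (freq >= 3.0) & (freq <= 8.0)
        assert np.allclose(nps.nps_db, 10 * np.log10(ws.power[keep] / wr.power[keep]))

    def test_identical_sample_and_reference_is_zero_db(self):
        freq = np.fft.rfftfreq(256, d=1 / 40.0)
        w = BlockSpectrum(freq, np.full(freq.size, 3.7))
        att = rq.AttenuationSet(alpha_tissue=0.0, alpha_local=0.0, alpha_ref=0.0)
        nps = rq.normalize_and_compensate(w, w, att, 0.0, 0.0, 0.0, (3.0, 8.0))
        assert np.allclose(nps.nps_db, 0.0)


class TestSpectralFit:
    def test_exact_linear_input(self):
        freq = np.linspace(5.1, 8.3, 40)
        nps = rq.NPSEstimate(freq, -10.0 + 2.0 * freq, band=(5.1, 8.3))
        feats = rq.fit_spectral_features(nps)
        assert feats.ss == pytest.approx(2.0)
        assert feats.si == pytest.approx(-10.0)
        assert feats.mbf == pytest.approx(-10.0 + 2.0 * 6.7)

    def test_constant_spectrum(self):
        freq = np.linspace(3.0, 8.0, 30)
        feats = rq.fit_spectral_features(rq.NPSEstimate(freq, np.full(30, -4.2), band=(3, 8)))
        assert feats.ss == pytest.approx(0.0, abs=1e-12)
        assert feats.si == pytest.approx(-4.2)
        assert feats.mbf == pytest.approx(-4.2)

    def test_matches_normal_equations_oracle(self, rng):
        freq = np.linspace(3.0, 8.0, 64)
        y = -8.0 + 1.3 * freq + 0.3 * rng.standard_normal(64)
        feats = rq.fit_spectral_features(rq.NPSEstimate(freq, y, band=(3, 8)))
        X = np.column_stack([freq, np.ones_like(freq)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
        assert feats.ss == pytest.approx(slope, abs=1e-10)
        assert feats.si == pytest.approx(intercept, abs=1e-10)

    def test_too_few_bins_rejected(self):
        nps = rq.NPSEstimate(np.array([5.0, 6.0]), np.array([0.0, 1.0]), band=(5, 6))
        with pytest.raises(ValueError, match="3"):
            rq.fit_spectral_features(nps)

    @settings(derandomize=True, max_examples=40)
    @given(
        slope=st.floats(-5, 5),
        intercept=st.floats(-40, 10),
        noise_seed=st.integers(0, 1000),
    )
    def test_regression_identity_mbf(self, slope, intercept, noise_seed):
        """MBF ≡ SI + SS·f_center for any spectrum (1e-9 dB)."""
        freq = np.linspace(5.1, 8.3, 32)
        noise = np.random.default_rng(noise_seed).normal(0, 1, 32)
        feats = rq.fit_spectral_features(
            rq.NPSEstimate(freq, intercept + slope * freq + noise, band=(5.1, 8.3))
        )
        assert feats.mbf == pytest.approx(feats.si + feats.ss * 6.7, abs=1e-9)


class TestLocalAttenuation:
    def _synthetic(self, alpha_m, alpha_r, n_depths=8, band=(3.0, 8.0)):
        """Noiseless normalized dB spectra obeying the depth decay model."""
        freq = np.linspace(band[0], band[1], 32)
        z = np.linspace(1.0, 2.0, n_depths)
        # two-way dB decay of the phantom-normalized spectrum
        db = -2.0 * (alpha_m - alpha_r) * freq[None, :] * z[:, None]
        return db, z, freq

    def test_recovers_exact_synthetic_slope(self):
        db, z, freq = self._synthetic(alpha_m=1.5, alpha_r=0.7861)
        res = estimate_local_attenuation(db, z, freq, alpha_ref=0.7861)
        assert res.alpha_local == pytest.approx(1.5, abs=1e-9)
        assert not res.flagged and not res.used_fallback

    def test_depth_independent_spectra_give_zero(self):
        db = np.zeros((6, 16))
        z = np.linspace(1, 2, 6)
        freq = np.linspace(3, 8, 16)
        res = estimate_local_attenuation(db, z, freq, alpha_ref=0.0)
        assert res.alpha_local == pytest.approx(0.0, abs=1e-12)

    def test_sample_equals_phantom_recovers_alpha_ref(self):
        db, z, freq = self._synthetic(alpha_m=0.7861, alpha_r=0.7861)
        res = estimate_local_attenuation(db, z, freq, alpha_ref=0.7861)
        assert res.alpha_local == pytest.approx(0.7861, abs=1e-9)

    def test_insufficient_depths_fall_back(self):
        db = np.zeros((2, 16))
        res = estimate_local_attenuation(
            db, np.array([1.0, 1.1]), np.linspace(3, 8, 16), alpha_ref=0.7861
        )
        assert res.used_fallback and res.alpha_local == 1.0

    def test_implausible_estimate_flagged_and_replaced(self):
        db, z, freq = self._synthetic(alpha_m=5.0, alpha_r=0.0)  # outside [0, 3]
        res = estimate_local_attenuation(db, z, freq, alpha_ref=0.0)
        assert res.flagged and res.alpha_local == 1.0

    def test_recovers_simulated_tumor_attenuation(self, st_small, st_bank):
        """Depth-slope estimate on simulated frames recovers the medium slope."""
        from refqus.core import build_block_grid, rasterize_roi
        from refqus.spectral import band_mask

        med = rq.MediumSpec(100.0, 3e3, 1.5)
        roi = rq.ROIPolygon([(1.5, 4.0), (13.5, 4.0), (13.5, 24.0), (1.5, 24.0)])
        frames = [rq.simulate_frame(med, st_small, seed=4200 + k) for k in range(4)]
        mask = rasterize_roi(roi, frames[0])
        grid = build_block_grid(mask, frames[0])
        n_ax = grid.n_axial
        nfft = next_pow2(4 * n_ax)
        freq = np.fft.rfftfreq(nfft, d=1 / st_small.sampling_rate_mhz)
        keep = band_mask(freq, (3.0, 8.0))
        win = np.hanning(n_ax)
        starts = sorted({b.axial_start for b in grid})
        z = np.array([(s + n_ax / 2) * st_small.axial_pitch_mm / 10 for s in starts])
        db = np.zeros((len(starts), keep.sum()))
        for fr in frames:
            for i, s in enumerate(starts):
                W = (
                    np.abs(np.fft.rfft(fr.samples[s : s + n_ax] * win[:, None], nfft, axis=0)) ** 2
                ).mean(axis=1)
                db[i] += 10 * np.log10(W[keep] / st_bank.spectrum_at(s, n_ax, nfft)[keep])
        db /= len(frames)
        res = estimate_local_attenuation(db, z, freq[keep], alpha_ref=0.7861)
        assert res.alpha_local == pytest.approx(1.5, abs=0.3)
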