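"""Tests of the RF simulator: pulse bandwidth, spectral fidelity, speckle
statistics, attenuation behaviour, determinism, and cohort structure."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import hilbert

import refqus as rq
from refqus.synthesis import CohortSpec, GroupParams, Layer


@pytest.mark.parametrize("profile", [rq.ST, rq.CL15], ids=lambda p: p.name)
def test_pulse_band_matches_profile(profile):
    """The −6 dB band of |FFT(pulse)|² must match the profile band within 5%."""
    pulse, fs = rq.synthesize_pulse(profile)
    lo, hi = rq.measured_band(pulse, fs)
    assert lo == pytest.approx(profile.band_low_mhz, rel=0.05)
    assert hi == pytest.approx(profile.band_high_mhz, rel=0.05)
    assert np.max(np.abs(pulse)) == pytest.approx(1.0)


def test_zero_bandwidth_profile_rejected():
    with pytest.raises(ValueError, match="band_low < center < band_high"):
        rq.TransducerProfile(
            name="degenerate",
            center_frequency_mhz=6.0,
            band_low_mhz=6.0,
            band_high_mhz=6.0,
            sampling_rate_mhz=40.0,
            lateral_pitch_mm=0.1,
            axial_pitch_mm=0.0193,
            n_lines=10,
            n_samples=100,
            focal_depth_mm=20.0,
        )


def test_unreachable_band_names_profile():
    import dataclasses

    # construction itself enforces fs > 2·band_high, naming the profile
    with pytest.raises(ValueError, match="bad"):
        dataclasses.replace(rq.ST, name="bad", sampling_rate_mhz=15.0)


def test_same_seed_is_bit_identical(st_small, phantom_medium):
    a = rq.simulate_frame(phantom_medium, st_small, seed=5)
    b = rq.simulate_frame(phantom_medium, st_small, seed=5)
    assert np.array_equal(a.samples, b.samples)
    c = rq.simulate_frame(phantom_medium, st_small, seed=6)
    assert not np.array_equal(a.samples, c.samples)


def test_medium_deeper_than_frame_rejected(st_small):
    deep = rq.MediumSpec(50.0, 1e4, 0.5, depth_extent_cm=100.0)
    with pytest.raises(ValueError, match="deeper"):
        rq.simulate_frame(deep, st_small, seed=0)


def test_zero_attenuation_power_is_depth_independent(st_small):
    med = rq.MediumSpec(20.0, 1e7, 0.0, speed_of_sound_m_s=1488.0)
    powers = np.zeros(2)
    n_frames = 6
    for k in range(n_frames):
        fr = rq.simulate_frame(med, st_small, seed=700 + k)
        i1 = int(6.0 / st_small.axial_pitch_mm)
        i2 = int(18.0 / st_small.axial_pitch_mm)
        w = int(4.0 / st_small.axial_pitch_mm)
        powers[0] += np.mean(fr.samples[i1 : i1 + w] ** 2)
        powers[1] += np.mean(fr.samples[i2 : i2 + w] ** 2)
    assert powers[0] == pytest.approx(powers[1], rel=0.1)


def test_ensemble_spectrum_proportional_to_theory(st_small, phantom_medium):
    """Attenuation-compensated ensemble power spectrum tracks |P|²·σ_theory
    with correlation > 0.98 over the −6 dB band (≥100 lines averaged)."""
    med = phantom_medium
    nfft = 2048
    i0 = int(8.0 / st_small.axial_pitch_mm)
    i1 = int(16.0 / st_small.axial_pitch_mm)
    win = np.hanning(i1 - i0)
    acc = None
    for k in range(4):  # 4 × 128 lines
        fr = rq.simulate_frame(med, st_small, seed=900 + k)
        P = np.abs(np.fft.rfft(fr.samples[i0:i1] * win[:, None], nfft, axis=0)) ** 2
        acc = P.mean(axis=1) if acc is None else acc + P.mean(axis=1)
    freq = np.fft.rfftfreq(nfft, d=1.0 / st_small.sampling_rate_mhz)
    z_mid_cm = (i0 + i1) / 2.0 * st_small.axial_pitch_mm / 10.0
    comp = np.exp(4.0 * med.attenuation_db_mhz_cm / 8.6859 * freq * z_mid_cm)
    measured = acc * comp
    pulse, fs = rq.synthesize_pulse(st_small)
    p2 = np.abs(np.fft.rfft(pulse, nfft)) ** 2
    model = p2 * rq.theoretical_bsc(
        freq, med.a_eff_um, med.acoustic_concentration_per_cm3,
        speed_of_sound=med.speed_of_sound_m_s,
    )
    band = (freq >= 3.0) & (freq <= 8.0)
    r = np.corrcoef(measured[band], model[band])[0, 1]
    assert r > 0.98


def test_envelope_is_rayleigh(st_small):
    """Fully developed speckle of a homogeneous high-density medium has a
    Rayleigh envelope (KS p > 0.01 at n = 10⁴ decorrelated samples).

    A lossless medium keeps the envelope scale depth-stationary, and the
    envelope is subsampled beyond the pulse correlation length so the KS
    test sees approximately independent draws.  The line model integrates
    scatterers over a single lateral pitch, so "high density" here means
    many more scatterers per cell than the generator's default.
    """
    med = rq.MediumSpec(
        20.0, 1e7, 0.0, speed_of_sound_m_s=1488.0, scatterer_density=64.0
    )
    i0 = int(6.0 / st_small.axial_pitch_mm)
    i1 = int(20.0 / st_small.axial_pitch_mm)
    vals = []
    for k in range(16):
        fr = rq.simulate_frame(med, st_small, seed=500 + k)
        env = np.abs(hilbert(fr.samples[i0:i1], axis=0))
        vals.append(env[::150, :].ravel())
    sample = np.concatenate(vals)[:10_000]
    scale = np.sqrt(np.mean(sample**2) / 2.0)
    p = stats.kstest(sample, stats.rayleigh(scale=scale).cdf).pvalue
    assert p > 0.01


class TestReferencePhantom:
    def test_default_properties(self, phantom_frames_st):
        _, spec = phantom_frames_st
        assert spec.attenuation_slope == pytest.approx(0.7861)
        assert spec.speed_of_sound == pytest.approx(1488.0)

    def test_zero_frames_rejected(self, st_small, phantom_medium):
        with pytest.raises(ValueError, match="n_frames"):
            rq.simulate_reference_phantom(st_small, phantom_medium, n_frames=0)

    def test_heterogeneous_medium_rejected(self, st_small, phantom_medium):
        with pytest.raises(ValueError, match="homogeneous"):
            rq.simulate_reference_phantom(
                st_small, phantom_medium, n_frames=1, heterogeneity_scale=0.1
            )

    def test_bsc_table_increasing_in_rayleigh_regime(self, phantom_frames_st):
        """Small beads scatter in the Rayleigh regime: σ_r rises with f."""
        _, spec = phantom_frames_st
        band = (spec.freq_mhz >= 3.0) & (spec.freq_mhz <= 8.3)
        assert np.all(np.diff(spec.bsc[band]) > 0)


@pytest.fixture(scope="module")
def tiny_profiles():
    st = rq.ST.scaled(n_lines=12, n_samples=1300)
    cl = rq.CL15.scaled(n_lines=6, n_samples=1000)
    return st, cl


class TestCohort:

    def test_cohort_structure(self, tiny_profiles):
        """6 benign + 22 malignant patients, each with both systems' frames."""
        spec = CohortSpec(
            n_patients_benign=6,
            n_patients_malignant=22,
            profiles=tiny_profiles,
            seed=3,
        )
        cohort = rq.generate_cohort(spec)
        assert len(cohort.patients) == 28
        groups = [p.group for p in cohort.patients]
        assert groups.count("benign") == 6 and groups.count("malignant") == 22
        for p in cohort.patients:
            assert set(p.frames) == {"ST", "CL15"}
            n = len(p.frames["ST"])
            assert 4 <= n <= 6
            assert len(p.frames["CL15"]) == n == len(p.rois) == len(p.truth)

    def test_zero_heterogeneity_constant_parameters(self, tiny_profiles):
        spec = CohortSpec(
            n_patients_benign=1,
            n_patients_malignant=1,
            profiles=tiny_profiles,
            heterogeneity_scale=0.0,
            seed=4,
        )
        cohort = rq.generate_cohort(spec)
        for p in cohort.patients:
            for key in ("esd_um", "conc_db", "atten_db_mhz_cm"):
                vals = [t[key] for t in p.truth]
                assert np.ptp(vals) == 0.0

    def test_fixed_seed_reproducible(self, tiny_profiles):
        spec = CohortSpec(
            n_patients_benign=1, n_patients_malignant=1,
            profiles=tiny_profiles, seed=9,
        )
        a = rq.generate_cohort(spec)
        b = rq.generate_cohort(spec)
        for pa, pb in zip(a.patients, b.patients):
            for sysname in pa.frames:
                for fa, fb in zip(pa.frames[sysname], pb.frames[sysname]):
                    assert np.array_equal(fa.samples, fb.samples)

    def test_frames_per_patient_validated(self, tiny_profiles):
        with pytest.raises(ValueError, match=r"\[4, 6\]"):
            CohortSpec(frames_per_patient=(2, 3), profiles=tiny_profiles)

    def test_effect_size_between_groups(self, tiny_profiles):
        """Benign and malignant group means differ in the configured directions."""
        spec = CohortSpec(
            n_patients_benign=4, n_patients_malignant=4,
            profiles=tiny_profiles, seed=5,
        )
        truth = rq.generate_cohort(spec).truth_table()
        g = truth.groupby("group")["esd_um"].mean()
        assert g["malignant"] > g["benign"]
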