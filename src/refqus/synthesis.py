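"""Synthetic RF frame generation for phantoms and tumor-bearing media.

The simulator is the generative counterpart of the Gaussian form-factor
backscatter model: each scan line is the convolution of a transducer pulse
with a random scatterer reflectivity train whose amplitude spectrum is
shaped by sqrt(σ_theory(f)), so that the ensemble backscattered power
spectrum is proportional to the theoretical BSC by construction.
Depth-dependent two-way attenuation exp(−4 α_Np f z) (power) is applied in
the frequency domain over 1 mm depth segments.  No diffraction or beam
model is included: the estimators this package implements operate on
beamformed RF, and the reference-phantom division cancels system terms, so
focusing effects are deliberately not modelled.

Two virtual transducers are provided as presets: a cart-based linear array
(``ST``: 6.3 MHz center, 3–8 MHz band, 40 MHz sampling) and a handheld
linear array (``CL15``: 6.7 MHz center, 5.1–8.3 MHz band, 30 MHz
sampling), with the corresponding pixel pitches and image sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .backscatter import PhantomSpec, theoretical_bsc
from .constants import ASSUMED_SOUND_SPEED_M_S, DB_PER_NEPER
from .core import RFFrame

__all__ = [
    "TransducerProfile",
    "MediumSpec",
    "GroupParams",
    "CohortSpec",
    "Layer",
    "ScattererCloud",
    "ST",
    "CL15",
    "reference_phantom_medium",
    "synthesize_pulse",
    "measured_band",
    "simulate_frame",
    "simulate_layered_frame",
    "simulate_reference_phantom",
    "generate_cohort",
    "Cohort",
    "PatientRecord",
]


@dataclass(frozen=True)
class TransducerProfile:
    """Virtual linear-array transducer and imaging geometry.

    Frequencies in MHz, pitches and focal depth in mm.  The −6 dB two-way
    band is [band_low, band_high]; the sampling rate must exceed twice the
    upper band edge.
    """

    name: str
    center_frequency_mhz: float
    band_low_mhz: float
    band_high_mhz: float
    sampling_rate_mhz: float
    lateral_pitch_mm: float
    axial_pitch_mm: float
    n_lines: int
    n_samples: int
    focal_depth_mm: float

    def __post_init__(self) -> None:
        if not (self.band_low_mhz < self.center_frequency_mhz < self.band_high_mhz):
            raise ValueError(
                f"profile {self.name!r}: need band_low < center < band_high"
            )
        if self.sampling_rate_mhz <= 2.0 * self.band_high_mhz:
            raise ValueError(
                f"profile {self.name!r}: sampling rate must exceed 2·band_high"
            )
        if self.n_lines <= 0 or self.n_samples <= 0:
            raise ValueError(f"profile {self.name!r}: image size must be positive")
        if self.lateral_pitch_mm <= 0 or self.axial_pitch_mm <= 0:
            raise ValueError(f"profile {self.name!r}: pitches must be positive")

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_low_mhz, self.band_high_mhz)

    @property
    def bandwidth_mhz(self) -> float:
        return self.band_high_mhz - self.band_low_mhz

    @property
    def depth_mm(self) -> float:
        return self.n_samples * self.axial_pitch_mm

    @property
    def width_mm(self) -> float:
        return self.n_lines * self.lateral_pitch_mm

    @property
    def axial_resolution_mm(self) -> float:
        """Nominal axial resolution c / (2 B)."""
        return ASSUMED_SOUND_SPEED_M_S / (2.0 * self.bandwidth_mhz * 1e6) * 1e3

    def scaled(self, n_lines: int | None = None, n_samples: int | None = None):
        """A copy with a reduced image size (same band, pitches, rates)."""
        return replace(
            self,
            n_lines=n_lines or self.n_lines,
            n_samples=n_samples or self.n_samples,
        )


#: Cart-based system preset (L14-5/60 style linear array).
ST = TransducerProfile(
    name="ST",
    center_frequency_mhz=6.3,
    band_low_mhz=3.0,
    band_high_mhz=8.0,
    sampling_rate_mhz=40.0,
    lateral_pitch_mm=0.1174,
    axial_pitch_mm=0.0193,
    n_lines=510,
    n_samples=2064,
    focal_depth_mm=17.5,
)

#: Handheld wireless system preset.
CL15 = TransducerProfile(
    name="CL15",
    center_frequency_mhz=6.7,
    band_low_mhz=5.1,
    band_high_mhz=8.3,
    sampling_rate_mhz=30.0,
    lateral_pitch_mm=0.2604,
    axial_pitch_mm=0.0256,
    n_lines=192,
    n_samples=1586,
    focal_depth_mm=20.03,
)


@dataclass(frozen=True)
class MediumSpec:
    """Acoustic ground truth of a (locally homogeneous) scattering medium.

    Attributes
    ----------
    effective_scatterer_diameter_um : float
        ESD = 2·a_eff, µm.
    acoustic_concentration_per_cm3 : float
        n̄γ₀² per cm³, linear scale.
    attenuation_db_mhz_cm : float
        Frequency-proportional attenuation slope.
    speed_of_sound_m_s : float
        Sound speed entering the form-factor model (tissue 1540).
    scatterer_density : float
        Scatterers per resolution cell — a simulation-only nuisance
        parameter; ≥ 10 gives fully developed (Rayleigh) speckle.
    depth_extent_cm / lateral_extent_cm : float or None
        Region populated with scatterers; ``None`` means "fill the frame".
    """

    effective_scatterer_diameter_um: float
    acoustic_concentration_per_cm3: float
    attenuation_db_mhz_cm: float
    speed_of_sound_m_s: float = 1540.0
    scatterer_density: float = 12.0
    depth_extent_cm: float | None = None
    lateral_extent_cm: float | None = None

    def __post_init__(self) -> None:
        if self.effective_scatterer_diameter_um <= 0:
            raise ValueError("scatterer diameter must be positive")
        if self.acoustic_concentration_per_cm3 <= 0:
            raise ValueError("acoustic concentration must be positive")
        if self.attenuation_db_mhz_cm < 0:
            raise ValueError("attenuation slope must be non-negative")
        if self.speed_of_sound_m_s <= 0 or self.scatterer_density <= 0:
            raise ValueError("speed of sound and scatterer density must be positive")

    @property
    def a_eff_um(self) -> float:
        return self.effective_scatterer_diameter_um / 2.0


def reference_phantom_medium(
    attenuation_db_mhz_cm: float = 0.7861,
    speed_of_sound_m_s: float = 1488.0,
    esd_um: float = 20.0,
    concentration_per_cm3: float = 1.0e7,
    scatterer_density: float = 12.0,
) -> MediumSpec:
    """Default homogeneous reference phantom medium.

    Emulates a glass-bead gelatin phantom: small beads (Rayleigh regime
    over the transducer bands), attenuation slope 0.7861 dB/(MHz·cm),
    sound speed 1488 m/s.
    """
    return MediumSpec(
        effective_scatterer_diameter_um=esd_um,
        acoustic_concentration_per_cm3=concentration_per_cm3,
        attenuation_db_mhz_cm=attenuation_db_mhz_cm,
        speed_of_sound_m_s=speed_of_sound_m_s,
        scatterer_density=scatterer_density,
    )


# ---------------------------------------------------------------------------
# pulse synthesis
# ---------------------------------------------------------------------------


def synthesize_pulse(profile: TransducerProfile) -> tuple[np.ndarray, float]:
    """Synthesize the transducer's two-way pulse at the profile sampling rate.

    The pulse is built in the frequency domain with a piecewise-Gaussian
    amplitude spectrum peaked at the center frequency, with independent
    half-widths below and above it chosen so the −6 dB points of the
    power spectrum |P(f)|² fall exactly at the band edges (the measured
    band of a pulse-echo system need not be symmetric about its spectral
    peak).  The zero-phase time pulse is truncated where its envelope has
    decayed by 60 dB and normalized to unit peak amplitude.

    Returns
    -------
    pulse : ndarray
        Real pulse samples.
    fs_mhz : float
        Sampling rate (same as the profile's).
    """
    fc = profile.center_frequency_mhz
    f_lo, f_hi = profile.band
    if f_hi - f_lo <= 0:
        raise ValueError(f"profile {profile.name!r}: zero bandwidth requested")
    if f_hi >= profile.sampling_rate_mhz / 2.0:
        raise ValueError(
            f"profile {profile.name!r}: band unreachable at sampling rate "
            f"{profile.sampling_rate_mhz} MHz"
        )
    fs = profile.sampling_rate_mhz
    n = 4096
    freq = np.fft.rfftfreq(n, d=1.0 / fs)
    # |P(f)|^2 = exp(-((f-fc)/sig)^2) drops by 6 dB (10^-0.6) at the band edges
    ln_edge = 0.6 * np.log(10.0)
    sig_lo = (fc - f_lo) / np.sqrt(ln_edge)
    sig_hi = (f_hi - fc) / np.sqrt(ln_edge)
    sig = np.where(freq < fc, sig_lo, sig_hi)
    amp = np.exp(-0.5 * ((freq - fc) / sig) ** 2)  # amplitude = sqrt(power)
    pulse = np.fft.fftshift(np.fft.irfft(amp, n))
    envelope = np.abs(_analytic(pulse))
    keep = envelope >= envelope.max() * 10.0 ** (-60.0 / 20.0)
    idx = np.where(keep)[0]
    pulse = pulse[idx[0] : idx[-1] + 1]
    return pulse / np.max(np.abs(pulse)), fs


def _analytic(x: np.ndarray) -> np.ndarray:
    from scipy.signal import hilbert

    return hilbert(x)


def measured_band(pulse: np.ndarray, fs_mhz: float, drop_db: float = 6.0) -> tuple[float, float]:
    """−`drop_db` band edges of |FFT(pulse)|², by linear interpolation."""
    n = max(8192, 4 * pulse.size)
    freq = np.fft.rfftfreq(n, d=1.0 / fs_mhz)
    power = np.abs(np.fft.rfft(pulse, n)) ** 2
    p_db = 10.0 * np.log10(power / power.max() + 1e-300)
    above = p_db >= -drop_db
    i = np.where(above)[0]
    i0, i1 = i[0], i[-1]

    def cross(ia, ib):
        # linear interpolation of the -drop_db crossing between bins ia, ib
        f1, f2, d1, d2 = freq[ia], freq[ib], p_db[ia], p_db[ib]
        if d1 == d2:
            return f1
        return f1 + ((-drop_db) - d1) * (f2 - f1) / (d2 - d1)

    lo = cross(i0 - 1, i0) if i0 > 0 else freq[0]
    hi = cross(i1, i1 + 1) if i1 + 1 < freq.size else freq[-1]
    return lo, hi


# ---------------------------------------------------------------------------
# scatterer clouds and frame simulation
# ---------------------------------------------------------------------------


@dataclass
class ScattererCloud:
    """Continuous-space scatterer field shared between virtual systems."""

    depth_mm: np.ndarray  # axial positions
    lateral_mm: np.ndarray  # lateral positions
    amplitude: np.ndarray  # unit-variance reflectivity amplitudes
    extent_depth_mm: float
    extent_width_mm: float

    @property
    def density_per_mm2(self) -> float:
        return self.amplitude.size / (self.extent_depth_mm * self.extent_width_mm)


def make_cloud(
    depth_mm: float,
    width_mm: float,
    density_per_mm2: float,
    rng: np.random.Generator,
) -> ScattererCloud:
    """Draw a uniform random scatterer cloud with Gaussian amplitudes."""
    n = rng.poisson(density_per_mm2 * depth_mm * width_mm)
    return ScattererCloud(
        depth_mm=rng.uniform(0.0, depth_mm, n),
        lateral_mm=rng.uniform(0.0, width_mm, n),
        amplitude=rng.standard_normal(n),
        extent_depth_mm=depth_mm,
        extent_width_mm=width_mm,
    )


def cloud_density_for(medium: MediumSpec, profile: TransducerProfile) -> float:
    """Scatterers per mm² realizing ``medium.scatterer_density`` per cell."""
    cell_mm2 = profile.axial_resolution_mm * profile.lateral_pitch_mm
    return medium.scatterer_density / cell_mm2


@dataclass(frozen=True)
class Layer:
    """A depth slab [z_top, z_bottom] (mm) with homogeneous properties."""

    z_top_mm: float
    z_bottom_mm: float
    medium: MediumSpec

    def __post_init__(self) -> None:
        if self.z_bottom_mm <= self.z_top_mm:
            raise ValueError("layer must have positive thickness")


def simulate_layered_frame(
    layers: Sequence[Layer],
    profile: TransducerProfile,
    seed: int | np.random.SeedSequence | None = None,
    cloud: ScattererCloud | None = None,
) -> RFFrame:
    """Simulate one RF frame of a depth-layered medium.

    Per scan line, scatterers are binned to the nearest (sample, line)
    position; the train is normalized to unit per-sample variance, shaped
    in the frequency domain by sqrt(σ_theory) of the layer the segment
    lies in, attenuated by the cumulative two-way path exp(−2 α_Np f z),
    and finally convolved with the transducer pulse.  Attenuation and
    spectral shaping are applied per 1 mm depth segment.
    """
    if not layers:
        raise ValueError("need at least one layer")
    layers = sorted(layers, key=lambda L: L.z_top_mm)
    depth_mm = profile.depth_mm
    width_mm = profile.width_mm
    if layers[-1].z_bottom_mm > depth_mm + 1e-9:
        raise ValueError(
            "medium deeper (%.1f mm) than the frame depth n_samples·axial_pitch "
            "(%.1f mm)" % (layers[-1].z_bottom_mm, depth_mm)
        )
    rng = np.random.default_rng(seed)
    if cloud is None:
        density = max(cloud_density_for(L.medium, profile) for L in layers)
        cloud = make_cloud(depth_mm, width_mm, density, rng)

    n_ax, n_lat = profile.n_samples, profile.n_lines
    # bin scatterers onto the sample grid of this system
    iz = np.rint(cloud.depth_mm / profile.axial_pitch_mm).astype(int)
    ix = np.rint(cloud.lateral_mm / profile.lateral_pitch_mm).astype(int)
    ok = (iz >= 0) & (iz < n_ax) & (ix >= 0) & (ix < n_lat)
    train = np.zeros((n_ax, n_lat))
    np.add.at(train, (iz[ok], ix[ok]), cloud.amplitude[ok])
    # unit per-sample variance so the shaped power spectrum equals σ_theory
    lam = cloud.density_per_mm2 * profile.axial_pitch_mm * profile.lateral_pitch_mm
    train /= np.sqrt(lam)

    freq = np.fft.rfftfreq(n_ax, d=1.0 / profile.sampling_rate_mhz)
    pulse, _ = synthesize_pulse(profile)
    pulse_spec = np.fft.rfft(np.fft.ifftshift(_center_pad(pulse, n_ax)))

    # per-layer sqrt(σ_theory) shaping filters
    shape_filters = {}
    for L in layers:
        m = L.medium
        sigma = theoretical_bsc(
            freq, m.a_eff_um, m.acoustic_concentration_per_cm3,
            speed_of_sound=m.speed_of_sound_m_s,
        )
        shape_filters[id(L)] = np.sqrt(sigma)

    def layer_at(z_mm: float) -> Layer | None:
        for L in layers:
            if L.z_top_mm - 1e-9 <= z_mm < L.z_bottom_mm + 1e-9:
                return L
        return None

    def cumulative_attenuation_db_mhz(z_mm: float) -> float:
        # ∫0^z α dz' in dB/MHz (z in cm); gaps between layers are lossless
        total = 0.0
        for L in layers:
            seg = max(0.0, min(z_mm, L.z_bottom_mm) - L.z_top_mm)
            total += L.medium.attenuation_db_mhz_cm * seg / 10.0
        return total

    seg_len = max(1, round(1.0 / profile.axial_pitch_mm))  # 1 mm segments
    spec = np.zeros((freq.size, n_lat), dtype=complex)
    buf = np.zeros_like(train)
    for s0 in range(0, n_ax, seg_len):
        s1 = min(s0 + seg_len, n_ax)
        seg = train[s0:s1]
        if not np.any(seg):
            continue
        z_mid_mm = (s0 + s1) / 2.0 * profile.axial_pitch_mm
        L = layer_at(z_mid_mm)
        if L is None:
            continue
        att_db_mhz = cumulative_attenuation_db_mhz(z_mid_mm)
        g = shape_filters[id(L)] * np.exp(-2.0 * att_db_mhz / DB_PER_NEPER * freq)
        buf[:] = 0.0
        buf[s0:s1] = seg
        spec += np.fft.rfft(buf, axis=0) * g[:, None]
    rf = np.fft.irfft(spec * pulse_spec[:, None], n=n_ax, axis=0)
    return RFFrame(rf, profile=profile)


def _center_pad(pulse: np.ndarray, n: int) -> np.ndarray:
    """Place the pulse at the center of a length-n buffer."""
    if pulse.size > n:
        raise ValueError("pulse longer than the frame")
    out = np.zeros(n)
    start = (n - pulse.size) // 2
    out[start : start + pulse.size] = pulse
    return out


def simulate_frame(
    medium: MediumSpec,
    profile: TransducerProfile,
    seed: int | np.random.SeedSequence | None = None,
    cloud: ScattererCloud | None = None,
) -> RFFrame:
    """Simulate one RF frame of a homogeneous medium.

    Reproducible: the same seed yields an identical frame.
    """
    depth_mm = (
        medium.depth_extent_cm * 10.0 if medium.depth_extent_cm else profile.depth_mm
    )
    return simulate_layered_frame(
        [Layer(0.0, depth_mm, medium)], profile, seed=seed, cloud=cloud
    )


def simulate_reference_phantom(
    profile: TransducerProfile,
    medium: MediumSpec | None = None,
    n_frames: int = 8,
    seed: int | np.random.SeedSequence | None = None,
    heterogeneity_scale: float = 0.0,
) -> tuple[list[RFFrame], PhantomSpec]:
    """Simulate frames of a homogeneous reference phantom plus its ground truth.

    Returns the frames and a :class:`PhantomSpec` whose BSC table is the
    theoretical BSC of the phantom medium evaluated on a fine frequency
    grid covering the transducer band.
    """
    if heterogeneity_scale != 0.0:
        raise ValueError("reference phantom must be homogeneous (heterogeneity 0)")
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    medium = medium or reference_phantom_medium()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    frames = [simulate_frame(medium, profile, seed=s) for s in root.spawn(n_frames)]
    f_table = np.arange(0.25, profile.sampling_rate_mhz / 2.0 + 0.05, 0.05)
    sigma_r = theoretical_bsc(
        f_table,
        medium.a_eff_um,
        medium.acoustic_concentration_per_cm3,
        speed_of_sound=medium.speed_of_sound_m_s,
    )
    phantom = PhantomSpec(
        attenuation_slope=medium.attenuation_db_mhz_cm,
        speed_of_sound=medium.speed_of_sound_m_s,
        freq_mhz=f_table,
        bsc=sigma_r,
    )
    return frames, phantom


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Per-group distribution of tumor medium parameters (means + spreads)."""

    esd_um: float
    concentration_per_cm3: float
    attenuation_db_mhz_cm: float
    esd_rel_spread: float = 0.10
    concentration_spread_db: float = 1.5
    attenuation_rel_spread: float = 0.10


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic multi-patient two-system cohort.

    Defaults emulate a 28-patient benign/malignant breast cohort imaged by
    both virtual transducers, with 4–6 frames per patient and a
    tissue-attenuation background of 1 dB/(MHz·cm) above the tumor.
    ``heterogeneity_scale`` is the relative frame-to-frame variation of
    tumor parameters within a patient (a proxy for tumor heterogeneity
    across imaging planes).
    """

    n_patients_benign: int = 6
    n_patients_malignant: int = 22
    frames_per_patient: tuple[int, int] = (4, 6)
    benign: GroupParams = field(
        default_factory=lambda: GroupParams(90.0, 1.0e4, 0.8)
    )
    malignant: GroupParams = field(
        default_factory=lambda: GroupParams(120.0, 3.0e3, 1.5)
    )
    heterogeneity_scale: float = 0.05
    seed: int = 0
    profiles: tuple[TransducerProfile, TransducerProfile] = (ST, CL15)
    tumor_top_mm: float = 10.0
    tumor_bottom_mm: float = 22.0
    background: MediumSpec = field(
        default_factory=lambda: MediumSpec(
            effective_scatterer_diameter_um=60.0,
            acoustic_concentration_per_cm3=1.0e4,
            attenuation_db_mhz_cm=1.0,
        )
    )
    scatterer_density: float = 12.0

    def __post_init__(self) -> None:
        lo, hi = self.frames_per_patient
        if not (4 <= lo <= hi <= 6):
            raise ValueError("frames_per_patient must lie within [4, 6]")
        if self.n_patients_benign < 0 or self.n_patients_malignant < 0:
            raise ValueError("patient counts must be non-negative")
        if self.heterogeneity_scale < 0:
            raise ValueError("heterogeneity_scale must be non-negative")
        for p in self.profiles:
            if self.tumor_bottom_mm > p.depth_mm:
                raise ValueError(
                    f"tumor deeper than frame of profile {p.name!r}"
                )


@dataclass
class PatientRecord:
    """One synthetic patient: per-system frames, shared ROIs, ground truth."""

    patient_id: str
    group: str  # "benign" | "malignant"
    frames: dict  # system name -> list[RFFrame]
    rois: list  # one ROIPolygon per frame (shared across systems)
    truth: list  # per-frame dicts of medium parameters


@dataclass
class Cohort:
    """A generated synthetic cohort."""

    spec: CohortSpec
    patients: list[PatientRecord]

    @property
    def system_names(self) -> tuple[str, str]:
        return tuple(p.name for p in self.spec.profiles)

    def truth_table(self):
        import pandas as pd

        rows = []
        for p in self.patients:
            for k, t in enumerate(p.truth):
                rows.append({"patient": p.patient_id, "group": p.group, "frame": k, **t})
        return pd.DataFrame(rows)


def _sample_medium(
    g: GroupParams, rng: np.random.Generator, het: float, base: dict | None = None
) -> dict:
    """Draw tumor medium parameters; ``base`` jitters an existing draw."""
    if base is None:
        esd = g.esd_um * float(np.exp(g.esd_rel_spread * rng.standard_normal()))
        conc_db = 10.0 * np.log10(g.concentration_per_cm3) + (
            g.concentration_spread_db * float(rng.standard_normal())
        )
        att = g.attenuation_db_mhz_cm * float(
            np.exp(g.attenuation_rel_spread * rng.standard_normal())
        )
    else:
        esd = base["esd_um"] * float(np.exp(het * rng.standard_normal()))
        conc_db = base["conc_db"] + 10.0 * het * float(rng.standard_normal())
        att = base["atten_db_mhz_cm"] * float(np.exp(het * rng.standard_normal()))
    return {"esd_um": esd, "conc_db": conc_db, "atten_db_mhz_cm": att}


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a paired two-system cohort with per-frame ground truth.

    Every frame of a patient is a distinct scatterer realization, but each
    realization is imaged by BOTH virtual transducers (system comparison
    therefore isolates device effects, emulating paired scanning).  All
    randomness derives deterministically from ``spec.seed``.
    """
    from .core import ROIPolygon

    p_a, p_b = spec.profiles
    groups = [("benign", spec.benign)] * spec.n_patients_benign + [
        ("malignant", spec.malignant)
    ] * spec.n_patients_malignant
    patients: list[PatientRecord] = []
    width_mm = min(p_a.width_mm, p_b.width_mm)
    depth_mm = min(p_a.depth_mm, p_b.depth_mm)
    # shared cloud density: the finer system's resolution cell sizes the count
    cell_mm2 = min(
        p.axial_resolution_mm * p.lateral_pitch_mm for p in (p_a, p_b)
    )
    density_per_mm2 = spec.scatterer_density / cell_mm2

    for idx, (group, gpar) in enumerate(groups):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))
        n_frames = int(rng.integers(spec.frames_per_patient[0], spec.frames_per_patient[1] + 1))
        base = _sample_medium(gpar, rng, spec.heterogeneity_scale)
        frames: dict[str, list[RFFrame]] = {p_a.name: [], p_b.name: []}
        rois, truth = [], []
        for k in range(n_frames):
            t = (
                _sample_medium(gpar, rng, spec.heterogeneity_scale, base)
                if spec.heterogeneity_scale > 0
                else dict(base)
            )
            tumor = MediumSpec(
                effective_scatterer_diameter_um=t["esd_um"],
                acoustic_concentration_per_cm3=10.0 ** (t["conc_db"] / 10.0),
                attenuation_db_mhz_cm=t["atten_db_mhz_cm"],
                scatterer_density=spec.scatterer_density,
            )
            layers = [
                Layer(0.0, spec.tumor_top_mm, spec.background),
                Layer(spec.tumor_top_mm, spec.tumor_bottom_mm, tumor),
            ]
            if spec.tumor_bottom_mm < depth_mm:
                layers.append(Layer(spec.tumor_bottom_mm, depth_mm, spec.background))
            cloud = make_cloud(
                depth_mm, width_mm, density_per_mm2, rng
            )
            for prof in (p_a, p_b):
                frames[prof.name].append(
                    simulate_layered_frame(layers, prof, cloud=cloud)
                )
            # rectangular ROI just inside the tumor slab, centred laterally
            x0, x1 = 0.1 * width_mm, 0.9 * width_mm
            z0, z1 = spec.tumor_top_mm, spec.tumor_bottom_mm
            rois.append(
                ROIPolygon([(x0, z0), (x1, z0), (x1, z1), (x0, z1)])
            )
            truth.append(t)
        patients.append(
            PatientRecord(
                patient_id=f"P{idx:03d}",
                group=group,
                frames=frames,
                rois=rois,
                truth=truth,
            )
        )
    return Cohort(spec=spec, patients=patients)
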