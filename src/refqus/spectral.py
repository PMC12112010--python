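"""Normalized power spectra, attenuation compensation, and MBF/SS/SI fits.

The reference phantom technique divides the sample's block-averaged power
spectrum W_s(f, z) by the spectrum W_r(f, z) of a homogeneous phantom at
the same depth, cancelling system-dependent factors (pulse spectrum,
diffraction, TGC).  The result is compensated for two-way attenuation with

    NPS(f) = W_s / W_r · exp(4 [α_m f z_m + α_i f z_i − α_r f z])

with attenuation slopes α in Np/(MHz·cm) (dB values divided by 8.6859),
f in MHz and depths in cm.  Linear regression of the dB NPS over the −6 dB
band yields the spectral slope (SS, dB/MHz), spectral intercept (SI, dB at
f = 0) and mid-band fit (MBF, dB at the band center).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DB_PER_NEPER, TWO_WAY_POWER_FACTOR

__all__ = [
    "BlockSpectrum",
    "NPSEstimate",
    "AttenuationSet",
    "SpectralFeatures",
    "block_power_spectrum",
    "compensation_factor",
    "normalize_and_compensate",
    "fit_spectral_features",
    "estimate_local_attenuation",
    "next_pow2",
]

_EPS = np.finfo(float).tiny


def next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


@dataclass
class BlockSpectrum:
    """Line-averaged power spectrum of one data block."""

    freq_mhz: np.ndarray
    power: np.ndarray
    flagged: bool = False  # all-zero input floored at machine epsilon


@dataclass
class NPSEstimate:
    """Normalized, attenuation-compensated power spectrum on a band."""

    freq_mhz: np.ndarray
    nps_db: np.ndarray
    band: tuple[float, float]
    block: object | None = None

    def __post_init__(self) -> None:
        self.freq_mhz = np.asarray(self.freq_mhz, dtype=float)
        self.nps_db = np.asarray(self.nps_db, dtype=float)
        if self.freq_mhz.ndim != 1 or np.any(np.diff(self.freq_mhz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(self.nps_db)):
            raise ValueError("NPS values must be finite")

    @property
    def nps_linear(self) -> np.ndarray:
        return 10.0 ** (self.nps_db / 10.0)


@dataclass
class AttenuationSet:
    """Attenuation slopes (dB/(MHz·cm)) entering the compensation exponent.

    alpha_tissue (α_i) is the intervening-tissue slope, default 1.0;
    alpha_local (α_m) is the tumor slope, usually estimated from the data;
    alpha_ref (α_r) comes from the reference phantom.  ``flagged`` marks a
    local estimate outside the plausibility window [0, 3] that was
    replaced by the fallback.
    """

    alpha_tissue: float = 1.0
    alpha_local: float = 1.0
    alpha_ref: float = 0.7861
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.alpha_tissue < 0 or self.alpha_ref < 0:
            raise ValueError("attenuation slopes must be non-negative")


@dataclass
class SpectralFeatures:
    """Line-fit features of the dB NPS: mbf = si + ss · f_center."""

    mbf: float  # dB
    ss: float  # dB/MHz
    si: float  # dB


def block_power_spectrum(
    block: np.ndarray, fs_mhz: float, nfft: int | None = None
) -> BlockSpectrum:
    """Hanning-windowed, line-averaged power spectrum of an RF block.

    Each line (column) is tapered with a Hanning window, zero-padded to
    the next power of two ≥ 4× the segment length, and |FFT|² is averaged
    across lines.  An all-zero block is floored at machine epsilon and
    flagged rather than raising.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]  # a single RF line
    if block.ndim != 2:
        raise ValueError("block must be 2-D (samples × lines)")
    n, n_lines = block.shape
    if n < 16:
        raise ValueError("block must have at least 16 samples per line")
    if nfft is None:
        nfft = next_pow2(4 * n)
    win = np.hanning(n)
    spec = np.fft.rfft(block * win[:, None], n=nfft, axis=0)
    power = np.mean(np.abs(spec) ** 2, axis=1)
    freq = np.fft.rfftfreq(nfft, d=1.0 / fs_mhz)
    flagged = not np.any(block)
    if flagged:
        power = np.full_like(power, np.finfo(float).eps)
    return BlockSpectrum(freq_mhz=freq, power=power, flagged=flagged)


def compensation_factor(
    freq_mhz: np.ndarray,
    atten: AttenuationSet,
    zi_cm: float,
    zm_cm: float,
    z_cm: float,
) -> np.ndarray:
    """Two-way attenuation compensation (linear power factor).

    ``exp(4 [α_m f z_m + α_i f z_i − α_r f z] / 8.6859)`` with α in
    dB/(MHz·cm); e.g. α_i = 1, f = 6 MHz, z_i = 1 cm alone gives
    exp(4·6/8.6859) ≈ 15.85 (+12 dB two-way).
    """
    f = np.asarray(freq_mhz, dtype=float)
    exponent = (
        TWO_WAY_POWER_FACTOR
        * f
        * (
            atten.alpha_local * zm_cm
            + atten.alpha_tissue * zi_cm
            - atten.alpha_ref * z_cm
        )
        / DB_PER_NEPER
    )
    return np.exp(exponent)


def band_mask(freq_mhz: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freq_mhz >= band[0]) & (freq_mhz <= band[1])


def normalize_and_compensate(
    sample: BlockSpectrum,
    reference: BlockSpectrum,
    atten: AttenuationSet,
    zi_cm: float,
    zm_cm: float,
    z_cm: float,
    band: tuple[float, float],
    block=None,
) -> NPSEstimate:
    """Reference-phantom normalization with attenuation compensation.

    The reference spectrum must come from phantom blocks at the matching
    depth.  Bins where the reference power is below machine epsilon are
    excluded.  With all attenuation slopes zero the result is exactly
    W_s / W_r in dB.
    """
    if sample.freq_mhz.shape != reference.freq_mhz.shape or not np.allclose(
        sample.freq_mhz, reference.freq_mhz
    ):
        raise ValueError("sample and reference spectra must share a frequency grid")
    keep = band_mask(sample.freq_mhz, band) & (reference.power > _EPS)
    if not np.any(keep):
        raise ValueError("no valid in-band frequency bins")
    f = sample.freq_mhz[keep]
    ratio = sample.power[keep] / reference.power[keep]
    nps_lin = ratio * compensation_factor(f, atten, zi_cm, zm_cm, z_cm)
    return NPSEstimate(
        freq_mhz=f,
        nps_db=10.0 * np.log10(np.maximum(nps_lin, _EPS)),
        band=band,
        block=block,
    )


def fit_spectral_features(nps: NPSEstimate) -> SpectralFeatures:
    """Ordinary least squares of the dB NPS on frequency.

    SS is the slope (dB/MHz), SI the intercept at f = 0, and MBF the
    fitted value at the band center (f_low + f_high)/2, so
    MBF = SI + SS · f_center identically.
    """
    if nps.freq_mhz.size < 3:
        raise ValueError("need at least 3 in-band frequency bins")
    ss, si = np.polyfit(nps.freq_mhz, nps.nps_db, 1)
    f_center = 0.5 * (nps.band[0] + nps.band[1])
    return SpectralFeatures(mbf=float(si + ss * f_center), ss=float(ss), si=float(si))


@dataclass
class LocalAttenuationResult:
    """Outcome of the depth-slope local attenuation estimate."""

    alpha_local: float  # dB/(MHz·cm)
    flagged: bool  # outside the plausibility window, fallback applied
    used_fallback: bool
    n_depths: int


def estimate_local_attenuation(
    normalized_db: np.ndarray,
    z_cm: np.ndarray,
    freq_mhz: np.ndarray,
    alpha_ref: float,
    *,
    fallback: float = 1.0,
    window: tuple[float, float] = (0.0, 3.0),
    min_depths: int = 3,
) -> LocalAttenuationResult:
    """Estimate the tumor attenuation slope from the depth decay of the NPS.

    Parameters
    ----------
    normalized_db : (n_blocks, n_f) array
        Phantom-normalized (uncompensated) block spectra in dB.
    z_cm : (n_blocks,) array
        Block-center depths.
    freq_mhz : (n_f,) array
        In-band frequency grid.
    alpha_ref : float
        Reference phantom attenuation slope, dB/(MHz·cm).

    Notes
    -----
    Spectra are averaged at each distinct depth; for every frequency a
    least-squares line of mean dB versus depth gives a slope s(f) in
    dB/cm.  Two-way power in dB decays at 2·α_dB·f per cm (equivalently,
    the neper-domain slope divided by the two-way factor 4), and the
    normalization makes the fitted slope measure the *contrast* against
    the phantom, so α_m(f) = −s(f)/2 + α_r·f; dividing by f and
    averaging over the band gives the slope in dB/(MHz·cm).  Estimates
    outside the plausibility window are replaced by the fallback (the
    assumed tissue slope) and flagged; so is an ROI spanning fewer than
    ``min_depths`` distinct depths.
    """
    normalized_db = np.atleast_2d(np.asarray(normalized_db, dtype=float))
    z_cm = np.asarray(z_cm, dtype=float)
    freq_mhz = np.asarray(freq_mhz, dtype=float)
    depths, inv = np.unique(np.round(z_cm, 9), return_inverse=True)
    if depths.size < min_depths:
        return LocalAttenuationResult(fallback, False, True, int(depths.size))
    # mean spectrum at each depth
    mean_db = np.zeros((depths.size, freq_mhz.size))
    for d in range(depths.size):
        mean_db[d] = normalized_db[inv == d].mean(axis=0)
    # per-frequency slope of mean dB vs depth (single shared design matrix)
    zc = depths - depths.mean()
    slopes = zc @ (mean_db - mean_db.mean(axis=0)) / (zc @ zc)  # dB/cm
    # dB slope → attenuation: two-way loss is 2 α_dB f z dB (Np slope / 4)
    alpha_f = -slopes / (TWO_WAY_POWER_FACTOR / 2.0) + alpha_ref * freq_mhz
    alpha_local = float(np.mean(alpha_f / freq_mhz))
    if not (window[0] <= alpha_local <= window[1]):
        return LocalAttenuationResult(fallback, True, True, int(depths.size))
    return LocalAttenuationResult(alpha_local, False, False, int(depths.size))
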