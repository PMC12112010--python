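# Methods

This note documents the models, conventions and design choices behind
`refqus`, and what its simulation-based validation does and does not show.

## Scattering and backscatter model

The backscatter coefficient of a medium of identical weak spherical
scatterers with effective radius a_eff and acoustic concentration n̄γ₀²
(number density × mean-square impedance contrast) is modelled with the
Gaussian form factor:

    σ(f) = π⁴/(36 c⁴) · f⁴ · a_eff⁶ · n̄γ₀² · FF_G,
    FF_G = exp(−0.827 · (2π f a_eff / c)²).

Units are handled internally in SI (f in Hz, lengths in m, n̄γ₀² per m³)
and the result is reported in 1/(cm·sr); user-facing parameters are µm for
diameters, per cm³ for concentration, MHz for frequency. In the f → 0
limit FF_G → 1 and σ ∝ f⁴ (Rayleigh scattering); the form factor halves at
0.827·(2πf a_eff/c)² = ln 2. The exponent carries the *squared* argument of
the form-factor literature. The sound speed default is 1540 m/s for tissue
and 1488 m/s for the reference phantom.

## RF synthesis

The simulator is the generative counterpart of this model, so estimator
validation closes the loop against known truth:

- **Pulse.** Built in the frequency domain with a piecewise-Gaussian
  amplitude spectrum peaked at the transducer's center frequency, with
  independent half-widths below/above it placing the −6 dB points of
  |P(f)|² exactly at the band edges. A pulse-echo band need not be
  symmetric about the spectral peak (the cart-system preset has center
  6.3 MHz with a 3–8 MHz band), which a single-σ Gaussian-modulated
  sinusoid cannot represent; the piecewise spectrum reproduces the
  measured band at the cost of a slight asymmetry of the time envelope.
  The zero-phase pulse is truncated at 60 dB envelope decay and peak-
  normalized.
- **Scatterer clouds.** Scatterers are drawn uniformly in continuous
  (depth, lateral) coordinates with Normal(0, 1) amplitudes, then binned
  to each system's (sample, line) grid — the same physical realization can
  therefore be imaged by both virtual transducers, as in paired scanning.
  `scatterer_density` (per axial-resolution × lateral-pitch cell,
  default 12) is a simulation-only nuisance parameter: second-order
  spectral statistics are density-independent by construction because the
  train is normalized to unit per-sample variance.
- **Spectral shaping and attenuation.** Each line's train is multiplied in
  the frequency domain by √σ_theory(f) of the layer it sits in, so the
  ensemble backscattered power spectrum is proportional to σ_theory with a
  proportionality constant shared between sample and reference — the
  reference-phantom division then cancels it along with the pulse
  spectrum. Two-way attenuation is applied as exp(−2 α_Np f z) in
  amplitude per 1 mm depth segment, with the cumulative α path integrated
  through the layer stack.
- **Not modelled.** Diffraction/focusing, elevational beam geometry,
  element directivity and harmonic propagation are deliberately absent:
  the estimators operate on beamformed RF and the phantom division cancels
  system terms, so a 1-D per-line model suffices for validating the
  estimation chain. Consequences: (i) simulated speckle approaches
  Rayleigh statistics only at densities well above the default, because
  one line integrates scatterers over a single lateral pitch rather than
  a beam width; (ii) cross-system texture differences here reflect only
  grid geometry and bandwidth, not the resolution/beam-shape differences
  that dominate texture disagreement on real scanners. Passing tests
  therefore validate the *estimators*, not the realism of clinical
  texture transfer.

## Geometry and depth bookkeeping

Frames use the imaging-system convention axial_pitch = c_assumed/(2 fs)
with c_assumed = 1540 m/s (this reproduces the presets' printed pitches);
the medium sound speed enters only the scattering model. Depths are
measured from the transducer face (axial index 0). For each analysis block,
z is the depth of the block center, z_i the tissue–tumor interface depth
(computed per lateral column as the shallowest ROI pixel, averaged over the
block's columns), and z_m = z − z_i, so z = z_i + z_m holds identically.

## Block decomposition and spectra

ROIs are polygonal; a pixel belongs to the ROI iff its center is inside
(even-odd rule). Square blocks of 2 mm (≈10 wavelengths) are laid with 94 %
overlap per axis; block pixel extents are rounded to integers, the step is
max(1, round(0.06 · extent)). A block is retained iff ≥ 70 % of its pixels
lie inside the ROI — the inclusion threshold is exposed in the
configuration since boundary handling is a genuine free choice; 70 %
tolerates boundary blocks without admitting mostly-outside windows. Block
spectra are Hanning-windowed per line, zero-padded to the next power of two
≥ 4× the segment length (stable band-edge interpolation), squared and
averaged over the block's lines. Reference spectra at each depth are pooled
over *all* lines of all phantom frames: the phantom is homogeneous, so
pooling minimizes reference variance.

## Attenuation

Three frequency-proportional slopes enter the compensation: α_i for
intervening tissue (default 1.0 dB/(MHz·cm), the conventional breast
value), α_r from the phantom (0.7861), and α_m for the tumor, estimated
from the data. All exponentials convert dB to nepers with the fixed
constant 8.6859 dB/Np; two-way power decays as exp(−4 α_Np f z), i.e.
2 α_dB f z in dB. The local estimator averages the phantom-normalized block
spectra at each depth, fits mean dB against depth per frequency, converts
the slope s(f) (dB/cm) via α_m(f) = −s(f)/2 + α_r·f — the −s/2 is the
dB-domain equivalent of dividing a neper-domain slope by the two-way
factor 4 — and averages α_m(f)/f over the band. Estimates outside a
plausibility window of [0, 3] dB/(MHz·cm), or ROIs spanning fewer than 3
distinct block depths, fall back to the assumed tissue slope and are
flagged; small-ROI slope fits are otherwise unstable and the plausible
breast range is well inside the window.

## Scatterer-size inversion

The measured BSC is fit to σ_theory in the dB domain: for each candidate
radius on a 2.5–150 µm grid (0.5 µm step) the optimal concentration is the
mean dB difference in closed form; the radius minimizing the residual sum
of squares is refined by a vectorized golden-section pass between its grid
neighbours (0.01 µm termination). dB-domain least squares is the standard
choice for reference-phantom QUS — it equalizes the weight of band edges
despite the f⁴ dynamic range — and makes ASD exactly invariant to constant
scaling of the spectrum (only AAC shifts, by the constant in dB). Minima on
the grid boundary are flagged. AAC is reported in dB relative to the
simulator's per-cm³ concentration unit; absolute calibration would require
an absolutely calibrated phantom table.

## Parametric maps and texture

Per-pixel maps of the five primary features average all overlapping block
estimates covering each pixel; pixels covered by no block are invalid and
excluded everywhere downstream. Maps are min–max quantized to 16 gray
levels (a configurable choice — texture values depend on it, and 16 is the
common practice for small ROIs), then 16 symmetric normalized GLCMs are
formed (angles 0°, 45°, 90°, 135° × per-axis step sizes 1–4 pixels; invalid
pixels are never paired) and contrast, correlation, homogeneity and energy
are averaged over them. Undefined correlations (zero marginal variance) are
excluded from the average rather than zero-filled. The pixel grid is *not*
resampled to isotropy: offsets are in pixels, and since axial/lateral
pitches differ per system this is a known inter-system texture confounder,
kept deliberately to mirror per-image processing.

## Aggregation and agreement statistics

Features are computed per block, averaged over blocks to frame values, and
averaged over a patient's 4–6 frames to tumor values (unweighted at both
levels; block-level pooling across frames is never done). RMSDf uses the
population (÷N) form; RMSD_USS pairs per-tumor means across systems, per
cohort and per band. Mann–Whitney U is two-sided at α = 0.05 per feature
with no multiplicity correction for the headline counts (a Bonferroni
table is emitted separately); the exact null distribution is used when the
pooled sample is ≤ 12 without ties, otherwise the normal approximation
with midranks, tie-corrected variance and 0.5 continuity correction. When
U equals its null mean the two-sided p is reported as exactly 1.
Bland–Altman uses the sample SD (n − 1) and limits at ±1.96 SD. Per-feature
statistics default to the common band, where the systems are comparable;
the band is configurable.

## Synthetic cohorts

`CohortSpec` emulates a paired two-system breast cohort: 6 benign + 22
malignant patients, 4–6 frames each, tumor slab between 10 and 22 mm depth
under a 1 dB/(MHz·cm) background, every frame imaged by both virtual
transducers over the same scatterer cloud. Group defaults (benign: ESD
90 µm, n̄γ₀² 10⁴/cm³, α 0.8; malignant: 120 µm, 3·10³/cm³, 1.5) encode the
qualitative clinical contrasts — larger effective scatterers, lower
backscatter intensity and higher attenuation in malignancy — at effect
sizes of roughly 2–3 patient-level SDs; between-patient spreads are 10 %
(1.5 dB for concentration) and within-patient frame-to-frame heterogeneity
defaults to 5 %. These are scientific defaults for a plausible synthetic
cohort, not fitted to any dataset.

## Problem sizes used in validation

The test suite and the reproduction script validate on reduced image sizes
— typically 128 scan lines (64/28 for two-system cohort studies) and
frames ~27 mm deep — which preserve the bands, pitches and sampling rates
the estimators are sensitive to while keeping each study in the seconds-to-
minutes range on one CPU: the self-normalization study uses 20 frames, the
recovery study 5 frames per diameter, the attenuation study 20
realizations, and the bandwidth study 10–20 replicate cohorts of 2 patients
× 4 frames. All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning, so every result is exactly
reproducible.

## Known limitations

- No beam/diffraction model: focusing-dependent spectral bias and
  resolution-driven texture effects are out of scope (see above).
- The phantom's BSC table is generated from σ_theory for a small-bead
  medium rather than from a measured bead-size distribution; the table is
  exact for the simulated world but idealized relative to a physical
  phantom.
- Attenuation is strictly linear in frequency; dispersive or power-law
  media are not modelled.
- The local-attenuation estimator assumes the ROI is deep enough to span
  ≥ 3 block depths and that the overlying tissue path is constant across
  the ROI's lateral extent.
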