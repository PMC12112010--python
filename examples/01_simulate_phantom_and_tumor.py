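"""Simulate RF frames of a reference phantom and a tumor-bearing medium.

Builds the two virtual transducers, synthesizes their pulses, simulates a
homogeneous reference phantom and a layered tumor medium, and prints basic
properties of the generated RF data.
"""

import numpy as np

import refqus as rq
from refqus.synthesis import Layer

# reduced image sizes keep this demo fast; bands/pitches are the presets'
st = rq.ST.scaled(n_lines=128, n_samples=1400)

pulse, fs = rq.synthesize_pulse(st)
lo, hi = rq.measured_band(pulse, fs)
print(f"{st.name} pulse: {pulse.size} samples at {fs:g} MHz, "
      f"-6 dB band {lo:.2f}-{hi:.2f} MHz (design {st.band_low_mhz}-{st.band_high_mhz})")

frames, phantom = rq.simulate_reference_phantom(st, n_frames=2, seed=1)
print(f"phantom: alpha = {phantom.attenuation_slope} dB/(MHz*cm), "
      f"c = {phantom.speed_of_sound} m/s, "
      f"sigma_r(6 MHz) = {phantom.bsc_at(np.array([6.0]))[0]:.3e} 1/(cm*sr)")

# tumor slab (ASD 100 um, AAC 34.8 dB, 1.5 dB/(MHz*cm)) under 10 mm of tissue
background = rq.MediumSpec(60.0, 1e4, 1.0)
tumor = rq.MediumSpec(100.0, 3e3, 1.5)
frame = rq.simulate_layered_frame(
    [Layer(0, 10, background), Layer(10, 22, tumor), Layer(22, st.depth_mm, background)],
    st, seed=2,
)
print(f"tumor frame: {frame.n_samples} x {frame.n_lines} samples, "
      f"RF rms = {frame.samples.std():.2e}")
print("The RF amplitude falls with depth because two-way attenuation "
      "exp(-4 a_Np f z) is applied to the scattered power.")
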