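"""Invert a backscatter coefficient for scatterer diameter and concentration.

First a noiseless sanity check (the inversion must return the generating
parameters exactly), then a full simulate-and-recover round trip.
"""

import numpy as np

import refqus as rq
from refqus.experiments import scatterer_recovery_study

# noiseless identity: sigma_theory(a = 50 um, n = 1e3) -> ASD 100 um, AAC 30 dB
freq = np.linspace(3.0, 8.0, 64)
sigma = rq.theoretical_bsc(freq, 50.0, 1e3)
fit = rq.fit_asd_aac(rq.BSCEstimate(freq, sigma))
print(f"noiseless inversion: ASD = {fit.asd_um:.2f} um (truth 100), "
      f"AAC = {fit.aac_db:.2f} dB (truth 30)")

# full chain: simulate tumors, estimate BSC per block, invert, average
res = scatterer_recovery_study(asd_um=(100.0,), n_frames=3, seed=5)
r = res[100.0]
print(f"simulated recovery: ASD = {r['asd_um']:.1f} um "
      f"({r['asd_rel_err_pct']:+.1f}% vs truth), "
      f"AAC error = {r['aac_err_db']:+.2f} dB over {r['n_frames']} frames")
print("Errors of a few percent reflect speckle noise and windowing bias; "
      "the Gaussian form factor makes sizes near 100 um well identified on "
      "the 3-8 MHz band.")
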