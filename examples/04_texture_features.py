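"""GLCM texture features of QUS parametric maps.

Builds per-pixel parametric maps of the five primary features from
overlapping block estimates, then computes contrast, correlation,
homogeneity and energy averaged over 16 co-occurrence configurations.
"""

import refqus as rq
from refqus.pipeline import PipelineConfig, ReferenceBank, analyze_frame
from refqus.synthesis import Layer

st = rq.ST.scaled(n_lines=128, n_samples=1400)
bank = ReferenceBank.simulate(st, n_frames=6, seed=20)
background = rq.MediumSpec(60.0, 1e4, 1.0)
tumor = rq.MediumSpec(120.0, 3e3, 1.2)
frame = rq.simulate_layered_frame(
    [Layer(0, 10, background), Layer(10, 22, tumor), Layer(22, st.depth_mm, background)],
    st, seed=21,
)
roi = rq.ROIPolygon([(1.5, 10.5), (13.5, 10.5), (13.5, 21.5), (1.5, 21.5)])
res = analyze_frame(frame, roi, bank, PipelineConfig())

mbf_map = res.maps["MBF"]
print(f"MBF parametric map: {mbf_map.valid_mask.sum()} valid pixels")
print("texture features (mean over 4 angles x 4 distances):")
for name in ("MBF", "SS", "SI", "ASD", "AAC"):
    row = {t: res.features[f"{name}-{t}"] for t in ("con", "cor", "hom", "ene")}
    print(f"  {name:>3}: CON={row['con']:7.3f}  COR={row['cor']:6.3f}  "
          f"HOM={row['hom']:5.3f}  ENE={row['ene']:6.4f}")
print("High homogeneity/correlation reflect the smoothness imposed by the "
      "94%-overlap block averaging; contrast grows with within-ROI "
      "heterogeneity of the underlying feature.")
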