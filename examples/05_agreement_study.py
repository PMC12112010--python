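"""Cross-system agreement study on a synthetic two-transducer cohort.

Generates a small paired cohort (every tumor imaged by both virtual
systems over the same scatterer realization), extracts the 25-feature set
per patient/system/band, and reports the consistency metrics.
"""

import refqus as rq
from refqus.pipeline import PipelineConfig
from refqus.synthesis import CohortSpec

st = rq.ST.scaled(n_lines=64, n_samples=1000)
cl = rq.CL15.scaled(n_lines=28, n_samples=780)
spec = CohortSpec(
    n_patients_benign=1, n_patients_malignant=2, frames_per_patient=(4, 4),
    profiles=(st, cl), tumor_top_mm=8.0, tumor_bottom_mm=17.0, seed=30,
)
cohort = rq.generate_cohort(spec)
report = rq.run_agreement_study(cohort, PipelineConfig(ref_frames=6))

tab = report.rmsd["malignant"].loc[["MBF", "SS", "SI", "ASD", "AAC"]]
print("malignant cohort, primary features:")
print(tab.round(3).to_string())
print()
print("RMSDf columns: frame-to-frame variation per system (tissue "
      "heterogeneity proxy). RMSD_USS: paired between-system differences; "
      "the common 5.1-8.3 MHz band removes most of the bandwidth-driven "
      "disagreement visible on the native bands.")
print()
print("cross-system Mann-Whitney p-values (common band):")
print(report.pvalues.loc[["MBF", "SS", "SI", "ASD", "AAC"]].round(3).to_string())
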