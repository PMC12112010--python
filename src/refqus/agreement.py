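"""Cross-system consistency metrics and agreement statistics.

Two root-mean-square deviation metrics quantify the sources of feature
variation:

- RMSDf = sqrt( Σᵢ (Q̂ − Qᵢ)² / N ) over the N frames of one tumor on one
  system (Q̂ the across-frame mean) — a proxy for tissue heterogeneity;
- RMSD_USS = sqrt( Σᵢ (Q̂_A,i − Q̂_B,i)² / n ) over the n paired tumor
  means of two systems — a proxy for system-induced differences.

Cross-system agreement per feature is tested with the two-sided
Mann–Whitney U test, and systematic bias is examined with Bland–Altman
analysis (limits of agreement at the mean difference ± 1.96 SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "rmsd_frames",
    "rmsd_between_systems",
    "mann_whitney_u",
    "bland_altman",
    "BlandAltman",
    "FeatureSet",
    "AgreementReport",
    "run_agreement_study",
    "FEATURE_NAMES",
    "PRIMARY_FEATURES",
]

PRIMARY_FEATURES = ("MBF", "SS", "SI", "ASD", "AAC")
FEATURE_NAMES = tuple(PRIMARY_FEATURES) + tuple(
    f"{m}-{t}" for m in PRIMARY_FEATURES for t in ("con", "cor", "hom", "ene")
)


def rmsd_frames(values) -> float:
    """Root-mean-square deviation of per-frame estimates about their mean.

    Returns NaN (flagged missing) for fewer than 2 frames.  Equals the
    population (÷N) standard deviation of the frame values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(np.sqrt(np.mean((v.mean() - v) ** 2)))


def rmsd_between_systems(a, b) -> float:
    """RMS difference of paired per-tumor means from two systems."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("need at least one complete pair")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mann_whitney_u(sample_a, sample_b, *, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when the pooled sample size is at
    most ``exact_max_n`` and there are no ties, and otherwise the normal
    approximation with midranks, tie-corrected variance and a 0.5
    continuity correction.  If every value in both samples is identical,
    the samples are indistinguishable and p = 1.

    Returns
    -------
    U : float
        The U statistic of the first sample.
    p : float
        Two-sided p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    u, p = float(res.statistic), float(res.pvalue)
    if u == a.size * b.size / 2.0:
        # U at its null mean: the two-sided p-value is 1 by symmetry
        # (the continuity correction would otherwise report p < 1)
        p = 1.0
    return u, p


@dataclass
class BlandAltman:
    """Bland–Altman agreement summary for paired measurements."""

    mean_diff: float
    sd_diff: float  # sample SD (n − 1)
    limits: tuple[float, float]  # mean_diff ± 1.96 · sd_diff
    means: np.ndarray  # pairwise means (x-axis of the plot)
    diffs: np.ndarray  # pairwise differences A − B

    def recompute_limits(self) -> tuple[float, float]:
        return (self.mean_diff - 1.96 * self.sd_diff, self.mean_diff + 1.96 * self.sd_diff)


def bland_altman(a, b) -> BlandAltman:
    """Bland–Altman analysis of paired values from two methods."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need at least 2 complete pairs")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return BlandAltman(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        limits=(mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff),
        means=(a + b) / 2.0,
        diffs=d,
    )


@dataclass
class FeatureSet:
    """The 25 features of one tumor on one system and analysis band."""

    patient_id: str
    system: str
    band: str  # "native" | "common"
    per_frame: "object"  # pandas DataFrame, frames × 25 features
    mean: "object" = None  # pandas Series of across-frame means

    def __post_init__(self) -> None:
        if self.mean is None:
            self.mean = self.per_frame.mean(axis=0)

    @property
    def n_frames(self) -> int:
        return len(self.per_frame)


@dataclass
class AgreementReport:
    """Tables of consistency metrics and agreement statistics.

    ``rmsd[cohort]`` holds, per feature, the per-system RMSDf (averaged
    over tumors) and the between-system RMSD_USS on native and common
    bands; ``pvalues`` has one row per feature and one column per cohort;
    ``bland_altman[(cohort, feature)]`` maps to a :class:`BlandAltman`.
    """

    rmsd: dict  # cohort -> DataFrame
    pvalues: "object"  # DataFrame: 25 features × cohorts
    pvalues_corrected: "object" = None  # Bonferroni column, informational only
    bland: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)

    def to_dir(self, out_dir) -> None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cohort, table in self.rmsd.items():
            table.to_csv(out / f"rmsd_{cohort}.csv")
        self.pvalues.to_csv(out / "pvalues.csv")
        if self.pvalues_corrected is not None:
            self.pvalues_corrected.to_csv(out / "pvalues_bonferroni.csv")
        ba = {
            f"{cohort}:{feat}": {
                "mean_diff": v.mean_diff,
                "sd_diff": v.sd_diff,
                "limits": list(v.limits),
                "means": v.means.tolist(),
                "diffs": v.diffs.tolist(),
            }
            for (cohort, feat), v in self.bland.items()
        }
        (out / "blandaltman.json").write_text(json.dumps(ba, indent=1, sort_keys=True))
        if self.exclusions:
            (out / "exclusions.log").write_text("\n".join(self.exclusions) + "\n")


def summarize_cohort(
    feature_sets: dict,
    patients_by_cohort: dict,
    systems: tuple[str, str],
    *,
    stats_band: str = "common",
) -> AgreementReport:
    """Build an :class:`AgreementReport` from per-tumor feature sets.

    ``feature_sets[(patient, system, band)]`` maps to a
    :class:`FeatureSet`; ``patients_by_cohort`` maps cohort name to the
    list of patient ids.
    """
    import pandas as pd

    sys_a, sys_b = systems
    rmsd_tables: dict[str, pd.DataFrame] = {}
    pcols: dict[str, pd.Series] = {}
    bland: dict = {}
    exclusions: list[str] = []

    for cohort, patients in patients_by_cohort.items():
        rows = {}
        paired: dict[str, dict[str, list[float]]] = {
            "native": {}, "common": {}
        }
        rmsdf: dict[str, dict[str, list[float]]] = {sys_a: {}, sys_b: {}}
        per_patient: dict[str, dict[str, list[float]]] = {sys_a: {}, sys_b: {}}
        for pid in patients:
            complete = all(
                (pid, s, b) in feature_sets
                for s in systems
                for b in ("native", "common")
            )
            if not complete:
                exclusions.append(f"{cohort}:{pid} missing a system; excluded from pairing")
            for feat in FEATURE_NAMES:
                for s in systems:
                    key = (pid, s, "native")
                    if key in feature_sets:
                        fs = feature_sets[key]
                        rmsdf[s].setdefault(feat, []).append(
                            rmsd_frames(fs.per_frame[feat].to_numpy())
                        )
                if complete:
                    for bandname in ("native", "common"):
                        pair = [
                            float(feature_sets[(pid, s, bandname)].mean[feat])
                            for s in systems
                        ]
                        paired[bandname].setdefault(feat, []).append(pair)
                    for s in systems:
                        per_patient[s].setdefault(feat, []).append(
                            float(feature_sets[(pid, s, stats_band)].mean[feat])
                        )
        for feat in FEATURE_NAMES:
            row = {}
            for s in systems:
                vals = np.asarray(rmsdf[s].get(feat, [np.nan]), dtype=float)
                row[f"RMSDf_{s}"] = float(np.nanmean(vals)) if vals.size else np.nan
            for bandname in ("native", "common"):
                pairs = np.asarray(paired[bandname].get(feat, []), dtype=float)
                row[f"RMSD_USS_{bandname}"] = (
                    rmsd_between_systems(pairs[:, 0], pairs[:, 1])
                    if pairs.size
                    else np.nan
                )
            rows[feat] = row
        rmsd_tables[cohort] = pd.DataFrame.from_dict(rows, orient="index")

        pvals = {}
        for feat in FEATURE_NAMES:
            va = np.asarray(per_patient[sys_a].get(feat, []), dtype=float)
            vb = np.asarray(per_patient[sys_b].get(feat, []), dtype=float)
            va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
            if va.size and vb.size:
                _, p = mann_whitney_u(va, vb)
            else:
                p = np.nan
            pvals[feat] = p
            if va.size >= 2 and va.size == vb.size:
                bland[(cohort, feat)] = bland_altman(va, vb)
        pcols[cohort] = pd.Series(pvals)

    pvalues = pd.DataFrame(pcols).reindex(list(FEATURE_NAMES))
    corrected = (pvalues * len(FEATURE_NAMES)).clip(upper=1.0)
    return AgreementReport(
        rmsd=rmsd_tables,
        pvalues=pvalues,
        pvalues_corrected=corrected,
        bland=bland,
        exclusions=exclusions,
    )


def run_agreement_study(cohort, config=None, out_dir=None) -> AgreementReport:
    """Full-chain agreement study on a synthetic (or loaded) cohort.

    Runs the feature pipeline for every patient, system and band, then
    assembles RMSD tables, Mann–Whitney p-values and Bland–Altman
    summaries.  Deterministic given the cohort and configuration.
    """
    from .pipeline import PipelineConfig, analyze_cohort

    config = config or PipelineConfig()
    feature_sets = analyze_cohort(cohort, config)
    patients_by_cohort: dict[str, list[str]] = {}
    for p in cohort.patients:
        patients_by_cohort.setdefault(p.group, []).append(p.patient_id)
    report = summarize_cohort(
        feature_sets,
        patients_by_cohort,
        cohort.system_names,
        stats_band=config.stats_band,
    )
    if out_dir is not None:
        report.to_dir(out_dir)
    return report
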