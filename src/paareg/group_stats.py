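"""Two-group ROI statistics and score correlations for an ALFF cohort.

The analysis mirrors a standard patient/control resting-state study: per
region, group means ± sd and a two-sample comparison (Welch t as the
default, with the classic one-way ANOVA F also reported — for two groups
the pooled-variance F equals t²), plus the Pearson correlation of each
region's ALFF with a cognitive scale score within the patient group.
Raw two-sided p-values are reported per region; a Bonferroni-adjusted
column is additionally emitted and labelled, since correcting across
regions is a known omission in this style of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_REGIONS",
    "CohortRecord",
    "RegionStat",
    "compare_groups",
    "pearson",
    "summarize_scores",
    "cohort_to_frame",
    "cohort_from_frame",
    "stats_to_frame",
]

#: the seven regions tracked by default: left/right middle temporal gyrus,
#: left fusiform gyrus, right inferior occipital gyrus, left middle
#: occipital gyrus, right posterior cerebellar lobe, right cerebellum
DEFAULT_REGIONS = ("LMTG", "RMTG", "LFG", "RIOG", "LMOG", "RPLC", "RC")

GROUPS = ("EG", "CG")  # experimental (patients) / control


@dataclass
class CohortRecord:
    """One subject: group membership, cognitive score, per-region ALFF."""

    subject_id: str
    group: str
    score: float
    regions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")
        for name, v in self.regions.items():
            if not np.isfinite(v):
                raise ValueError(f"region {name} value not finite for {self.subject_id}")


@dataclass
class RegionStat:
    region: str
    mean_eg: float
    sd_eg: float
    mean_cg: float
    sd_cg: float
    t: float          # Welch two-sample t (EG vs CG)
    p_t: float
    f: float          # one-way ANOVA F (pooled variance; = pooled t² for 2 groups)
    p_f: float
    p_bonferroni: float
    r: float = np.nan  # Pearson r of region ALFF vs score, within EG
    p_r: float = np.nan


def _region_values(records, region, group):
    vals = [rec.regions[region] for rec in records if rec.group == group]
    return np.asarray(vals, dtype=float)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs two equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    records,
    regions=None,
    correlate_with_score: bool = True,
) -> list[RegionStat]:
    """Per-region group comparison (and score correlation within EG).

    Requires at least two subjects per group.  Correlations are computed
    within the patient (EG) group, where the cognitive effect is measured.
    """
    records = list(records)
    regions = tuple(regions) if regions is not None else _infer_regions(records)
    for g in GROUPS:
        if sum(1 for rec in records if rec.group == g) < 2:
            raise ValueError(f"group {g} needs at least 2 subjects")
    eg_scores = np.array([rec.score for rec in records if rec.group == "EG"])
    out = []
    n_regions = len(regions)
    for region in regions:
        eg = _region_values(records, region, "EG")
        cg = _region_values(records, region, "CG")
        t_res = stats.ttest_ind(eg, cg, equal_var=False)
        f_res = stats.f_oneway(eg, cg)
        stat = RegionStat(
            region=region,
            mean_eg=float(eg.mean()),
            sd_eg=float(eg.std(ddof=1)),
            mean_cg=float(cg.mean()),
            sd_cg=float(cg.std(ddof=1)),
            t=float(t_res.statistic),
            p_t=float(t_res.pvalue),
            f=float(f_res.statistic),
            p_f=float(f_res.pvalue),
            p_bonferroni=float(min(1.0, t_res.pvalue * n_regions)),
        )
        if correlate_with_score and eg.size >= 3 and eg.std() > 0 and eg_scores.std() > 0:
            stat.r, stat.p_r = pearson(eg, eg_scores)
        out.append(stat)
    return out


def _infer_regions(records):
    regions = None
    for rec in records:
        keys = tuple(rec.regions)
        if regions is None:
            regions = keys
        elif set(keys) != set(regions):
            raise ValueError("records carry inconsistent region sets")
    if not regions:
        raise ValueError("no region values present")
    return regions


def summarize_scores(records) -> dict[str, dict[str, float]]:
    """Per-group mean ± sample sd of the cognitive score.

    With a single subject the sd is undefined and reported as NaN with
    ``sd_defined`` False.
    """
    out = {}
    for g in GROUPS:
        vals = np.array([rec.score for rec in records if rec.group == g], dtype=float)
        if vals.size == 0:
            continue
        sd_defined = vals.size >= 2
        out[g] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if sd_defined else float("nan"),
            "sd_defined": sd_defined,
        }
    if not out:
        raise ValueError("no subjects")
    return out


def cohort_to_frame(records) -> pd.DataFrame:
    """Tabular cohort: subject_id, group, score, one column per region."""
    rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id, "group": rec.group, "score": rec.score}
        row.update(rec.regions)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_frame(frame: pd.DataFrame) -> list[CohortRecord]:
    required = {"subject_id", "group", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    region_cols = [c for c in frame.columns if c not in required]
    return [
        CohortRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            score=float(row["score"]),
            regions={c: float(row[c]) for c in region_cols},
        )
        for _, row in frame.iterrows()
    ]


def stats_to_frame(region_stats) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in region_stats])
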