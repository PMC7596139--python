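"""Longitudinal and group statistics on expression scores and clinical ratings.

Covers the statistics used to characterize a DBS follow-up cohort: mean
+/- SD summaries, per-patient percent improvement, paired and two-sample
t tests, one-way repeated-measures ANOVA with Bonferroni post hoc tests,
and ROI standard-uptake-value-ratio (SUVR) summaries.  The per-patient
UPDRS and pattern-expression table of the 9-patient DBS cohort ships with
the package and is loaded by :func:`load_dbs_table`.

The repeated-measures ANOVA partitions the total sum of squares of an
n subjects x k timepoints table into time, subject and error components:
``F = MS_time / MS_error`` with df ``(k-1, (n-1)(k-1))`` and no sphericity
correction.  Complete cases only: subjects missing a timepoint are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import numpy.typing as npt
import pandas as pd
from scipy import stats

from .cohort import CohortMatrix
from .ssm import SubspacePartition

__all__ = [
    "StatResult",
    "LongitudinalTable",
    "load_dbs_table",
    "summarize",
    "percent_improvement",
    "paired_t",
    "rm_anova",
    "two_sample_t",
    "suvr_table",
]

TIMEPOINT_ORDER = ("baseline", "3mo", "12mo")


@dataclass
class StatResult:
    """A named test statistic with degrees of freedom and p-values."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    adjusted_p: dict[str, float] | None = None


@dataclass
class LongitudinalTable:
    """Subjects x ordered timepoints values with completeness flags.

    Missing cells (NaN) may occur only at the last timepoint, mirroring a
    follow-up design where dropout happens at the final scan.
    """

    values: npt.NDArray[np.float64]  # subjects x timepoints, NaN = missing
    subject_ids: tuple[str, ...]
    timepoints: tuple[str, ...] = TIMEPOINT_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x timepoints")
        if self.values.shape[1] != len(self.timepoints):
            raise ValueError("timepoint count mismatch")
        missing = np.isnan(self.values)
        if missing[:, :-1].any():
            raise ValueError("missing cells allowed only at the last timepoint")

    @property
    def complete_mask(self) -> np.ndarray:
        return ~np.isnan(self.values).any(axis=1)

    def complete_cases(self) -> np.ndarray:
        return self.values[self.complete_mask]


def load_dbs_table() -> pd.DataFrame:
    """Per-patient demographics, UPDRS and pattern z-scores of the DBS cohort."""
    with resources.files("pdrpnet.data").joinpath(
        "dbs_cohort_table.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def longitudinal_from_table(df: pd.DataFrame, prefix: str) -> LongitudinalTable:
    """Build a LongitudinalTable from fixture columns ``<prefix>_{baseline,3mo,12mo}``."""
    cols = [f"{prefix}_{t}" for t in TIMEPOINT_ORDER]
    return LongitudinalTable(
        values=df[cols].to_numpy(dtype=float),
        subject_ids=tuple(str(s) for s in df["subject"]),
    )


def summarize(values: npt.NDArray[np.float64]) -> tuple[float, float]:
    """Mean and sample SD (n-1), the table-reporting convention."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("cannot summarize an empty set of values")
    sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
    return float(v.mean()), sd


def percent_improvement(
    baseline: npt.NDArray[np.float64],
    followup: npt.NDArray[np.float64],
) -> tuple[np.ndarray, float]:
    """Per-subject percent change from baseline, and the group mean.

    ``100 * (baseline - followup) / baseline`` per subject, averaged over
    subjects (not the ratio of group means).
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up must pair by subject")
    if np.any(b == 0):
        raise ValueError("zero baseline value; percent change undefined")
    per = 100.0 * (b - f) / b
    return per, float(per.mean())


def paired_t(a, b) -> StatResult:
    """Two-sided paired-samples t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 equal-length pairs")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        if d.mean() == 0:
            return StatResult("paired_t", 0.0, (float(n - 1),), 1.0)
        return StatResult("paired_t", float("inf"), (float(n - 1),), 0.0)
    res = stats.ttest_rel(a, b)
    return StatResult(
        "paired_t", float(res.statistic), (float(n - 1),), float(res.pvalue)
    )


def rm_anova(
    table: LongitudinalTable | npt.NDArray[np.float64],
    complete_cases_only: bool = True,
    posthoc: bool = True,
) -> StatResult:
    """One-way repeated-measures ANOVA (time as the within-subject factor).

    Returns F with df ``(k-1, (n-1)(k-1))`` and, when ``posthoc`` is set,
    Bonferroni-adjusted pairwise paired-t p-values (raw p times the number
    of pairs, capped at 1).
    """
    if isinstance(table, LongitudinalTable):
        x = table.complete_cases() if complete_cases_only else table.values
        tps = table.timepoints
    else:
        x = np.asarray(table, dtype=float)
        if complete_cases_only:
            x = x[~np.isnan(x).any(axis=1)]
        tps = tuple(f"t{j}" for j in range(x.shape[1]))
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(
            f"repeated-measures ANOVA needs >= 2 complete subjects and "
            f">= 2 timepoints; got {n} x {k}"
        )
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subject = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_time = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_time
    df_time = k - 1
    df_error = (n - 1) * (k - 1)
    ms_time = ss_time / df_time
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f_val, p = (0.0, 1.0) if ms_time == 0 else (float("inf"), 0.0)
    else:
        f_val = ms_time / ms_error
        p = float(stats.f.sf(f_val, df_time, df_error))

    adjusted = None
    if posthoc and k >= 2:
        n_pairs = k * (k - 1) // 2
        adjusted = {}
        for i in range(k):
            for j in range(i + 1, k):
                res = paired_t(x[:, i], x[:, j])
                adjusted[f"{tps[i]}-{tps[j]}"] = min(
                    1.0, res.p_value * n_pairs
                )
    return StatResult(
        "rm_anova_F", f_val, (float(df_time), float(df_error)), p, adjusted
    )


def two_sample_t(group1, group2) -> StatResult:
    """Two-sided pooled-variance Student's t test."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("need >= 2 values per group")
    if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0 and g1.mean() == g2.mean():
        return StatResult(
            "two_sample_t", 0.0, (float(g1.size + g2.size - 2),), 1.0
        )
    res = stats.ttest_ind(g1, g2, equal_var=True)
    return StatResult(
        "two_sample_t",
        float(res.statistic),
        (float(g1.size + g2.size - 2),),
        float(res.pvalue),
    )


def suvr_table(
    cohort: CohortMatrix,
    partition: SubspacePartition | None = None,
) -> pd.DataFrame:
    """Group mean +/- SD of per-subject SUVR (activity over whole-brain mean).

    Each subject's ROI activities are divided by that subject's mean
    activity over all ROIs, then summarized per group.  When a subspace
    partition is given, only disease-subspace ROIs are reported, tagged by
    weight sign.
    """
    suvr = cohort.activities / cohort.activities.mean(axis=1, keepdims=True)
    roi_ids = cohort.roi_ids
    sign = {}
    if partition is not None:
        keep = list(partition.disease_rois)
        sign = {r: "+" for r in partition.positive_rois}
        sign.update({r: "-" for r in partition.negative_rois})
    else:
        keep = list(roi_ids)
    pos = {r: j for j, r in enumerate(roi_ids)}
    rows = []
    groups = sorted(set(cohort.group_labels))
    for roi in keep:
        j = pos[roi]
        row = {"roi": roi, "weight_sign": sign.get(roi, "")}
        for g in groups:
            vals = suvr[cohort.group_mask(g), j]
            mu, sd = summarize(vals)
            row[f"{g}_mean"] = mu
            row[f"{g}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)
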