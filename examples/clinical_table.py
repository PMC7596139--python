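"""Reproduce the published clinical statistics of the DBS follow-up cohort.

Loads the packaged per-patient table (UPDRS motor ratings and pattern
z-scores at baseline, 3 and 12 months) and recomputes every summary the
study reports.
"""

from pdrpnet import (
    load_dbs_table,
    longitudinal_from_table,
    paired_t,
    percent_improvement,
    rm_anova,
    summarize,
)

dbs = load_dbs_table()

for prefix, label, nd in (("updrs", "UPDRS", 1), ("pdrp", "pattern z", 2)):
    tab = longitudinal_from_table(dbs, prefix)
    means = [
        summarize(tab.values[:, j])[0] for j in range(3)
    ]
    print(
        f"{label}: baseline {means[0]:.{nd}f}, 3mo {means[1]:.{nd}f}, "
        f"12mo {means[2]:.{nd}f}"
    )
    res = rm_anova(tab)
    print(
        f"  rm-ANOVA on the 4 complete patients: "
        f"F({res.df[0]:.0f},{res.df[1]:.0f}) = {res.statistic:.3f}, "
        f"p = {res.p_value:.3f}"
    )

pt = paired_t(dbs["updrs_baseline"].to_numpy(), dbs["updrs_3mo"].to_numpy())
print(f"paired t, UPDRS baseline vs 3mo (9 pairs): p = {pt.p_value:.4f}")
_, imp = percent_improvement(
    dbs["updrs_baseline"].to_numpy(), dbs["updrs_3mo"].to_numpy()
)
print(f"mean per-patient motor improvement at 3 months: {imp:.0f}%")
print()
print(
    "Motor scores and network expression both drop sharply at 3 months and"
    " rebound by 12 months; the F tests quantify that time effect within"
    " patients."
)
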