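"""Track pattern expression through a deep-brain-stimulation follow-up.

Simulates a 9-patient DBS cohort scanned at baseline, 3 and 12 months
(plus 9 controls on the same scanner), scores every scan prospectively
against the derivation cohort's pattern, removes the cross-scanner offset
using the follow-up cohort's own controls, and runs the repeated-measures
ANOVA on the four patients with complete follow-up.
"""

import numpy as np

from pdrpnet import (
    SimulationConfig,
    apply_cohort_offset,
    derive_pattern,
    preprocess_profiles,
    rm_anova,
    score_cohort,
    simulate_cohort,
    simulate_longitudinal,
    z_reference,
)

SEED = 7  # one seed -> one planted pattern shared by both cohorts

cohort1, _ = simulate_cohort(SimulationConfig(seed=SEED))
pattern = derive_pattern(preprocess_profiles(cohort1))
hc1_raw = score_cohort(cohort1, pattern)[cohort1.group_mask("HC")]

follow, _ = simulate_longitudinal(SimulationConfig.dbs_cohort(seed=SEED))
raw = score_cohort(follow, pattern)
scores = z_reference(raw, hc1_raw)
scores = apply_cohort_offset(scores, scores.z_score[follow.group_mask("HC")])

tp = np.asarray(follow.timepoint_labels)
sid = np.asarray(follow.subject_ids)
grp = np.asarray(follow.group_labels)
complete = sorted(s for s in set(sid[grp == "PD"]) if np.sum(sid == s) == 3)

matrix = np.array(
    [
        [
            scores.z_corrected[(sid == s) & (tp == t)][0]
            for t in ("baseline", "3mo", "12mo")
        ]
        for s in complete
    ]
)
print("corrected pattern-expression z of complete-follow-up patients:")
for t, col in zip(("baseline", "3 months", "12 months"), matrix.T):
    print(f"  {t:>9}: {col.mean():.2f} +/- {col.std(ddof=1):.2f}")

res = rm_anova(matrix)
print(
    f"repeated-measures ANOVA: F({res.df[0]:.0f},{res.df[1]:.0f}) = "
    f"{res.statistic:.3f}, p = {res.p_value:.4f}"
)
print()
print(
    "Expression drops after stimulation and partially rebounds by 12"
    " months (the planted trajectory); the within-subject F test says the"
    " change over time is larger than the per-patient noise."
)
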