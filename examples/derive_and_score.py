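"""Derive a metabolic covariance pattern and score its expression.

Simulates a derivation cohort (33 controls + 33 patients, 95 ROIs) with a
planted disease pattern, runs SSM/PCA on the combined cohort, and z-scores
every subject's pattern expression against the healthy controls.
"""

import numpy as np

from pdrpnet import (
    SimulationConfig,
    derive_pattern,
    partition_subspace,
    preprocess_profiles,
    score_cohort,
    simulate_cohort,
    z_reference,
)

cohort, truth = simulate_cohort(SimulationConfig(seed=42))
pattern = derive_pattern(preprocess_profiles(cohort))
part = partition_subspace(pattern.z_weights, pattern.roi_ids, threshold=1.0)

raw = score_cohort(cohort, pattern)
scores = z_reference(raw, raw[cohort.group_mask("HC")])
hc_z = scores.z_score[cohort.group_mask("HC")]
pd_z = scores.z_score[cohort.group_mask("PD")]

recovery = abs(np.corrcoef(pattern.z_weights, truth.planted_weights)[0, 1])

print(f"PC1 variance accounted for: {pattern.vaf:.1%}")
print(
    f"disease subspace: {len(part.positive_rois)} positive + "
    f"{len(part.negative_rois)} negative salient ROIs (|z| >= 1)"
)
print(f"pattern recovery vs planted truth: |r| = {recovery:.3f}")
print(f"control z: {hc_z.mean():.2f} +/- {hc_z.std(ddof=1):.2f}  (0 +/- 1 by construction)")
print(f"patient z: {pd_z.mean():.2f} +/- {pd_z.std(ddof=1):.2f}")
print()
print(
    "The patient mean sits near the planted effect (2.74 control-SD units):"
    " an elevated z means the subject's metabolic profile expresses the"
    " disease covariance topography more strongly than a typical control."
)
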