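"""Assess which pattern region weights survive bootstrap resampling.

Resamples the derivation cohort with replacement (group sizes preserved),
re-derives the pattern 100 times, and flags ROIs whose weight exceeds 3.35
bootstrap standard deviations in magnitude.
"""

import numpy as np

from pdrpnet import SimulationConfig, bootstrap_pattern, simulate_cohort

cohort, truth = simulate_cohort(SimulationConfig(seed=5))
rel = bootstrap_pattern(cohort, n_boot=100, z_threshold=3.35, seed=5)

planted = np.zeros(95, dtype=bool)
planted[list(truth.salient_all)] = True

print(f"reliable ROIs (|Z| >= {rel.z_threshold}): {int(rel.mask.sum())} of 95")
print(
    f"planted salient ROIs flagged reliable: "
    f"{int(rel.mask[planted].sum())} of {int(planted.sum())}"
)
top = np.argsort(-np.abs(rel.boot_z))[:5]
print("most reliable regions:")
for j in top:
    print(
        f"  {rel.roi_ids[j]:<22} weight {rel.point_weights[j]:+.3f}  "
        f"Z {rel.boot_z[j]:+.1f}"
    )
print()
print(
    "A large |Z| means the region's contribution to the pattern is stable"
    " under resampling of subjects, not an artifact of particular scans."
)
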