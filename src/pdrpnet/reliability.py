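"""Bootstrap reliability of pattern region weights.

The derivation cohort is resampled with replacement (within group, so each
replicate keeps the original patient/control sizes), the pattern is
re-derived on each replicate, and each replicate's weights are sign-aligned
to the point estimate.  The reliability statistic per ROI is the point
estimate divided by the bootstrap SD of that weight (an inverse coefficient
of variation); regions with ``|Z|`` at or above the threshold (default
3.35) are flagged reliable.  An alternative statistic, bootstrap mean over
bootstrap SD, is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .cohort import CohortMatrix
from .ssm import derive_pattern, preprocess_profiles

__all__ = ["ReliabilityMap", "bootstrap_pattern"]


@dataclass
class ReliabilityMap:
    """Per-ROI bootstrap reliability Z values and the thresholded mask."""

    boot_z: npt.NDArray[np.float64]
    mask: npt.NDArray[np.bool_]
    point_weights: npt.NDArray[np.float64]
    boot_sd: npt.NDArray[np.float64]
    boot_mean: npt.NDArray[np.float64]
    n_boot: int
    z_threshold: float
    seed: int
    roi_ids: tuple[str, ...]


def bootstrap_pattern(
    cohort: CohortMatrix,
    n_boot: int = 100,
    z_threshold: float = 3.35,
    seed: int = 0,
    statistic: str = "point_over_sd",
    patient_group: str = "PD",
    control_group: str = "HC",
    max_retries: int = 20,
) -> ReliabilityMap:
    """Assess region-weight reliability by stratified bootstrap resampling.

    Parameters
    ----------
    statistic
        ``"point_over_sd"`` (default): point-estimate weight / bootstrap SD.
        ``"mean_over_sd"``: bootstrap-mean weight / bootstrap SD.

    Notes
    -----
    ROIs whose bootstrap SD is exactly zero (no resampling variability)
    get infinite Z and are included in the mask.  A replicate whose
    residual profiles carry no variance is redrawn, with a bounded number
    of retries.
    """
    if n_boot < 2:
        raise ValueError("need n_boot >= 2 to estimate a bootstrap SD")
    if statistic not in ("point_over_sd", "mean_over_sd"):
        raise ValueError(f"unknown reliability statistic {statistic!r}")
    point = derive_pattern(
        preprocess_profiles(cohort), patient_group, control_group
    )
    rng = np.random.default_rng([seed, cohort.n_subjects, n_boot])
    group_indices = {
        g: np.flatnonzero(cohort.group_mask(g))
        for g in (control_group, patient_group)
    }

    reps = np.empty((n_boot, cohort.n_rois))
    for b in range(n_boot):
        for _attempt in range(max_retries + 1):
            rows = np.concatenate(
                [
                    rng.choice(idx, size=idx.size, replace=True)
                    for idx in group_indices.values()
                ]
            )
            boot = CohortMatrix(
                activities=cohort.activities[rows],
                roi_ids=cohort.roi_ids,
                subject_ids=tuple(f"b{b}_{i}" for i in range(rows.size)),
                group_labels=tuple(
                    np.asarray(cohort.group_labels)[rows]
                ),
            )
            try:
                rep = derive_pattern(
                    preprocess_profiles(boot), patient_group, control_group
                )
            except ValueError:
                continue  # degenerate replicate: redraw
            break
        else:
            raise ValueError(
                f"bootstrap replicate {b} degenerate after "
                f"{max_retries} retries"
            )
        w = rep.weights
        # align replicate sign to the point estimate
        if float(w @ point.weights) < 0:
            w = -w
        reps[b] = w

    boot_sd = reps.std(axis=0, ddof=1)
    center = point.weights if statistic == "point_over_sd" else reps.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_z = np.where(
            boot_sd > 0,
            center / np.where(boot_sd > 0, boot_sd, 1.0),
            np.where(center != 0, np.sign(center) * np.inf, 0.0),
        )
    mask = np.abs(boot_z) >= z_threshold
    return ReliabilityMap(
        boot_z=boot_z,
        mask=mask,
        point_weights=point.weights,
        boot_sd=boot_sd,
        boot_mean=reps.mean(axis=0),
        n_boot=n_boot,
        z_threshold=z_threshold,
        seed=seed,
        roi_ids=cohort.roi_ids,
    )
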