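"""Scaled Subprofile Model / PCA derivation of a metabolic covariance pattern.

The model: log-transform strictly positive regional activities, remove each
subject's global mean log activity (multiplicative global scaling becomes an
additive offset in log space and is subtracted away), remove the derivation
cohort's mean regional profile, and take the first principal component of
the resulting subject residual profiles (SRP).  PC1's regional loadings form
the disease pattern; its subject scores separate patients from controls.

Region weights are reported both raw (unit Euclidean norm, the projection
basis) and standardized over ROIs (mean 0, SD 1), the scale on which the
disease subspace is defined as ``|z| >= 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from .cohort import CohortMatrix

__all__ = [
    "ResidualProfiles",
    "MetabolicPattern",
    "SubspacePartition",
    "preprocess_profiles",
    "derive_pattern",
    "standardize_region_weights",
    "partition_subspace",
]


@dataclass
class ResidualProfiles:
    """Doubly centered log activities of a derivation cohort.

    ``srp[i, j] = log a[i, j] - mean_j log a[i, :] - group_mean_profile[j]``
    where the group mean profile is the cohort mean of the subject-centered
    log values.  Rows therefore have mean ~0 and columns mean exactly 0 over
    the derivation cohort.
    """

    srp: npt.NDArray[np.float64]
    group_mean_profile: npt.NDArray[np.float64]
    subject_means: npt.NDArray[np.float64]
    roi_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]
    group_labels: tuple[str, ...]


@dataclass
class MetabolicPattern:
    """A disease-related covariance pattern (PC1 of the SRP matrix).

    Attributes
    ----------
    weights
        Raw PC1 regional loadings, unit Euclidean norm.  Scoring basis.
    z_weights
        Loadings standardized to mean 0, SD 1 over the ROI axis.
    vaf
        Fraction of subject x ROI variance accounted for by PC1.
    group_mean_profile
        Mean regional profile of the derivation cohort, stored so new
        subjects can be scored prospectively.
    derivation_scores
        PC1 subject scores of the derivation cohort (``srp @ weights``).
    orientation
        +1 if PC1 came out with patients above controls, -1 if it was
        flipped to enforce that convention.
    """

    weights: npt.NDArray[np.float64]
    z_weights: npt.NDArray[np.float64]
    vaf: float
    group_mean_profile: npt.NDArray[np.float64]
    derivation_scores: npt.NDArray[np.float64]
    orientation: int
    roi_ids: tuple[str, ...]
    derivation_subject_ids: tuple[str, ...] = field(default=())
    derivation_group_labels: tuple[str, ...] = field(default=())


@dataclass
class SubspacePartition:
    """Split of the ROI set into disease subspace and non-subspace.

    The disease subspace holds every ROI whose standardized region weight
    has absolute value at or above ``threshold`` (boundary inclusive), split
    by sign; the remainder is the non-subspace.
    """

    threshold: float
    positive_rois: tuple[str, ...]
    negative_rois: tuple[str, ...]
    non_subspace_rois: tuple[str, ...]

    @property
    def disease_rois(self) -> tuple[str, ...]:
        return self.positive_rois + self.negative_rois

    @property
    def n_disease(self) -> int:
        return len(self.positive_rois) + len(self.negative_rois)


def preprocess_profiles(cohort: CohortMatrix) -> ResidualProfiles:
    """Log-transform and doubly center a cohort into subject residual profiles.

    Global normalization is the subtraction of each subject's mean log
    activity, equivalent to dividing the profile by its geometric mean
    before the log.  The cohort mean profile is computed on the
    subject-centered log values and stored for prospective scoring.

    Raises
    ------
    ValueError
        If fewer than 3 subjects are supplied (the cohort positivity and
        completeness checks live in :class:`~pdrpnet.cohort.CohortMatrix`).
    """
    if cohort.n_subjects < 3:
        raise ValueError(
            f"need at least 3 subjects to form residual profiles, "
            f"got {cohort.n_subjects}"
        )
    log_act = np.log(cohort.activities)
    subject_means = log_act.mean(axis=1)
    centered = log_act - subject_means[:, None]
    group_mean_profile = centered.mean(axis=0)
    srp = centered - group_mean_profile[None, :]
    return ResidualProfiles(
        srp=srp,
        group_mean_profile=group_mean_profile,
        subject_means=subject_means,
        roi_ids=cohort.roi_ids,
        subject_ids=cohort.subject_ids,
        group_labels=cohort.group_labels,
    )


def derive_pattern(
    residuals: ResidualProfiles,
    patient_group: str = "PD",
    control_group: str = "HC",
) -> MetabolicPattern:
    """Extract PC1 of the residual profiles as the disease pattern.

    The singular value decomposition of the SRP matrix gives the principal
    axes directly; the first right singular vector is the pattern, and its
    squared singular value over the total is the variance accounted for.
    The sign is oriented so the mean derivation score of the patient group
    exceeds that of the control group.
    """
    srp = residuals.srp
    n_sub, n_roi = srp.shape
    if n_sub < 3 or n_roi < 2:
        raise ValueError("need >= 3 subjects and >= 2 ROIs to derive a pattern")
    groups = set(residuals.group_labels)
    if patient_group not in groups or control_group not in groups:
        raise ValueError(
            f"derivation cohort must contain both {patient_group!r} and "
            f"{control_group!r} subjects; has {sorted(groups)}"
        )
    total_var = float(np.sum(srp**2))
    if total_var == 0.0:
        raise ValueError("no variance to decompose: residual profiles are all zero")

    _, s, vt = np.linalg.svd(srp, full_matrices=False)
    weights = vt[0]
    vaf = float(s[0] ** 2 / np.sum(s**2))
    scores = srp @ weights

    pd_mask = np.asarray([g == patient_group for g in residuals.group_labels])
    hc_mask = np.asarray([g == control_group for g in residuals.group_labels])
    orientation = 1
    if scores[pd_mask].mean() < scores[hc_mask].mean():
        orientation = -1
        weights = -weights
        scores = -scores

    return MetabolicPattern(
        weights=weights,
        z_weights=standardize_region_weights(weights),
        vaf=vaf,
        group_mean_profile=residuals.group_mean_profile.copy(),
        derivation_scores=scores,
        orientation=orientation,
        roi_ids=residuals.roi_ids,
        derivation_subject_ids=residuals.subject_ids,
        derivation_group_labels=residuals.group_labels,
    )


def standardize_region_weights(
    weights: npt.NDArray[np.float64] | MetabolicPattern,
) -> npt.NDArray[np.float64]:
    """Z-transform region weights over the ROI axis (mean 0, SD 1).

    Uses the sample (n-1) SD, matching standard statistical-package
    behavior.  (With the population SD a standardized vector always has at
    least one entry of magnitude >= 1, which would make an all-non-salient
    pattern impossible by construction.)
    """
    if isinstance(weights, MetabolicPattern):
        weights = weights.weights
    w = np.asarray(weights, dtype=float)
    if w.size < 2:
        raise ValueError("need >= 2 region weights to standardize")
    sd = w.std(ddof=1)
    if sd == 0:
        raise ValueError("region weights have zero spread; cannot standardize")
    return (w - w.mean()) / sd


def partition_subspace(
    z_weights: npt.NDArray[np.float64],
    roi_ids: tuple[str, ...],
    threshold: float = 1.0,
) -> SubspacePartition:
    """Partition ROIs into disease subspace (``|z| >= threshold``) and rest."""
    if threshold <= 0:
        raise ValueError("salience threshold must be positive")
    z = np.asarray(z_weights, dtype=float)
    if z.size != len(roi_ids):
        raise ValueError("z_weights and roi_ids length mismatch")
    pos = tuple(r for r, v in zip(roi_ids, z) if v >= threshold)
    neg = tuple(r for r, v in zip(roi_ids, z) if v <= -threshold)
    non = tuple(r for r, v in zip(roi_ids, z) if abs(v) < threshold)
    return SubspacePartition(
        threshold=float(threshold),
        positive_rois=pos,
        negative_rois=neg,
        non_subspace_rois=non,
    )
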