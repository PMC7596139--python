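"""Prospective pattern-expression scoring (topographic profile rating).

A subject's expression of a fixed pattern is the inner product of their
residual profile (log activities, own global mean removed, derivation
cohort mean profile removed) with the pattern's region weights.  Raw
scores are in arbitrary units; they become interpretable after
Z-referencing against a healthy-control group, and — when a second cohort
was scanned on a different device — after subtracting the offset of that
cohort's own controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .cohort import CohortMatrix
from .ssm import MetabolicPattern

__all__ = ["ExpressionScores", "tpr_score", "score_cohort", "z_reference",
           "apply_cohort_offset"]


@dataclass
class ExpressionScores:
    """Per-subject expression scores on the raw, Z, and offset-corrected scales.

    ``z_score = (raw_tpr - hc_mean) / hc_sd`` with the reference controls
    mapping to mean 0, SD 1 exactly; ``z_corrected = z_score - offset``
    where the offset is the mean z of a secondary control group (0 until
    :func:`apply_cohort_offset` is applied).
    """

    raw_tpr: npt.NDArray[np.float64]
    z_score: npt.NDArray[np.float64]
    z_corrected: npt.NDArray[np.float64]
    reference_mean: float
    reference_sd: float
    offset: float
    subject_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    timepoint_labels: tuple[str, ...] | None = None


def tpr_score(
    subject_activities: npt.NDArray[np.float64],
    pattern: MetabolicPattern,
    roi_ids: tuple[str, ...] | None = None,
) -> float:
    """Score one subject's expression of a pattern (raw inner product).

    The profile is logged, centered on its own mean, the pattern's stored
    derivation mean profile is removed, and the residual is projected onto
    the pattern weights.  Prospective: the pattern is not modified, so
    derivation subjects scored through here reproduce their derivation
    scores exactly.
    """
    if roi_ids is not None:
        if len(roi_ids) != len(pattern.roi_ids):
            raise ValueError(
                f"profile has {len(roi_ids)} ROIs, pattern expects "
                f"{len(pattern.roi_ids)}"
            )
        for a, b in zip(roi_ids, pattern.roi_ids):
            if a != b:
                raise ValueError(
                    f"ROI order mismatch: profile has {a!r} where pattern "
                    f"expects {b!r}"
                )
    prof = np.asarray(subject_activities, dtype=float)
    if prof.ndim != 1 or prof.size != len(pattern.roi_ids):
        raise ValueError(
            f"expected a 1-D profile of length {len(pattern.roi_ids)}"
        )
    if np.any(prof <= 0) or not np.all(np.isfinite(prof)):
        raise ValueError("profile must be strictly positive and finite")
    log_prof = np.log(prof)
    resid = log_prof - log_prof.mean() - pattern.group_mean_profile
    return float(resid @ pattern.weights)


def score_cohort(cohort: CohortMatrix, pattern: MetabolicPattern) -> np.ndarray:
    """Raw TPR scores for every subject row of a cohort."""
    if cohort.roi_ids != pattern.roi_ids:
        first = next(
            (
                (a, b)
                for a, b in zip(cohort.roi_ids, pattern.roi_ids)
                if a != b
            ),
            None,
        )
        detail = f"; first mismatch {first[0]!r} vs {first[1]!r}" if first else ""
        raise ValueError("cohort/pattern ROI mismatch" + detail)
    return np.asarray(
        [tpr_score(row, pattern) for row in cohort.activities], dtype=float
    )


def z_reference(
    raw_scores: npt.NDArray[np.float64],
    hc_reference_scores: npt.NDArray[np.float64],
    subject_ids: tuple[str, ...] | None = None,
    group_labels: tuple[str, ...] | None = None,
    timepoint_labels: tuple[str, ...] | None = None,
) -> ExpressionScores:
    """Z-transform raw scores against a healthy-control reference group.

    The affine map sends the reference group to mean 0, SD 1 (sample SD,
    n-1 denominator) and is applied unchanged to every query score.
    """
    raw = np.asarray(raw_scores, dtype=float)
    ref = np.asarray(hc_reference_scores, dtype=float)
    if ref.size < 2:
        raise ValueError("need >= 2 reference scores to Z-reference")
    mu = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if sd == 0:
        raise ValueError("reference scores have zero SD; cannot Z-reference")
    z = (raw - mu) / sd
    n = raw.size
    return ExpressionScores(
        raw_tpr=raw,
        z_score=z,
        z_corrected=z.copy(),
        reference_mean=mu,
        reference_sd=sd,
        offset=0.0,
        subject_ids=subject_ids or tuple(f"s{i}" for i in range(n)),
        group_labels=group_labels or ("?",) * n,
        timepoint_labels=timepoint_labels,
    )


def apply_cohort_offset(
    scores: ExpressionScores,
    secondary_hc_z: npt.NDArray[np.float64],
) -> ExpressionScores:
    """Remove a cross-scanner offset estimated from secondary controls.

    The offset is the mean z-score of the secondary cohort's own healthy
    controls (scored against the primary reference); subtracting it centers
    those controls at exactly 0 without rescaling their SD.
    """
    sec = np.asarray(secondary_hc_z, dtype=float)
    if sec.size < 1:
        raise ValueError("need >= 1 secondary control z-score for the offset")
    offset = float(sec.mean())
    return ExpressionScores(
        raw_tpr=scores.raw_tpr,
        z_score=scores.z_score,
        z_corrected=scores.z_score - offset,
        reference_mean=scores.reference_mean,
        reference_sd=scores.reference_sd,
        offset=offset,
        subject_ids=scores.subject_ids,
        group_labels=scores.group_labels,
        timepoint_labels=scores.timepoint_labels,
    )
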