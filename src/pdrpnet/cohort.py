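"""The cohort container: subjects x ROIs metabolic activities plus metadata.

A :class:`CohortMatrix` is the canonical in-memory object exchanged between
the simulation, pattern-derivation, scoring and connectome stages.  ROI
order is fixed at construction and must match across all artifacts of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
import pandas as pd

__all__ = ["CohortMatrix"]


@dataclass
class CohortMatrix:
    """Subjects x ROIs strictly positive metabolic activities with metadata.

    Parameters
    ----------
    activities
        ``(n_subjects, n_rois)`` array of strictly positive values, in
        arbitrary metabolic-activity units.
    roi_ids
        Ordered ROI labels, one per column.
    subject_ids
        One identifier per row.  Longitudinal cohorts repeat the identifier
        across timepoints.
    group_labels
        Group assignment per row (e.g. ``"HC"`` / ``"PD"``).
    timepoint_labels
        Per-row timepoint tag (``"baseline"``, ``"3mo"``, ``"12mo"``) or
        ``None`` for cross-sectional cohorts.
    """

    activities: npt.NDArray[np.float64]
    roi_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    timepoint_labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.ndim != 2:
            raise ValueError("activities must be a 2-D subjects x ROIs array")
        n_sub, n_roi = self.activities.shape
        if n_roi != len(self.roi_ids):
            raise ValueError(
                f"{n_roi} activity columns but {len(self.roi_ids)} roi_ids"
            )
        if n_sub != len(self.subject_ids) or n_sub != len(self.group_labels):
            raise ValueError("per-subject metadata length mismatch")
        if self.timepoint_labels is not None and len(self.timepoint_labels) != n_sub:
            raise ValueError("timepoint_labels length mismatch")
        bad = np.argwhere(~np.isfinite(self.activities))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"missing/non-finite activity for subject "
                f"{self.subject_ids[i]!r}, ROI {self.roi_ids[j]!r}"
            )
        bad = np.argwhere(self.activities <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-positive activity for subject {self.subject_ids[i]!r}, "
                f"ROI {self.roi_ids[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.activities.shape[0]

    @property
    def n_rois(self) -> int:
        return self.activities.shape[1]

    def group_mask(self, group: str) -> npt.NDArray[np.bool_]:
        return np.asarray([g == group for g in self.group_labels])

    def select(self, mask: npt.NDArray[np.bool_] | list[bool]) -> "CohortMatrix":
        """Row subset preserving ROI order and metadata alignment."""
        mask = np.asarray(mask, dtype=bool)
        return CohortMatrix(
            activities=self.activities[mask],
            roi_ids=self.roi_ids,
            subject_ids=tuple(np.asarray(self.subject_ids)[mask]),
            group_labels=tuple(np.asarray(self.group_labels)[mask]),
            timepoint_labels=(
                None
                if self.timepoint_labels is None
                else tuple(np.asarray(self.timepoint_labels)[mask])
            ),
        )

    def subset_group(self, group: str) -> "CohortMatrix":
        return self.select(self.group_mask(group))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: subject_id, group, timepoint, then ROI columns."""
        meta = {
            "subject_id": list(self.subject_ids),
            "group": list(self.group_labels),
            "timepoint": (
                list(self.timepoint_labels)
                if self.timepoint_labels is not None
                else [""] * self.n_subjects
            ),
        }
        df = pd.DataFrame(meta)
        for j, roi in enumerate(self.roi_ids):
            df[roi] = self.activities[:, j]
        return df
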