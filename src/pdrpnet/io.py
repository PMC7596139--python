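"""File formats: cohort tables, pattern sidecars, NIfTI ROI extraction.

Cohort tables are TSV/CSV with a fixed header — ``subject_id``, ``group``,
``timepoint``, then the ROI columns in atlas order; shuffled ROI columns
with correct labels are reordered on load.  Patterns, simulation truth and
run manifests are JSON sidecars.  NIfTI volumes are read with nibabel;
ROI means are extracted against an integer label volume on the same grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RoiAtlas
from .cohort import CohortMatrix
from .simulate import SyntheticTruth
from .ssm import MetabolicPattern

__all__ = [
    "read_cohort_table",
    "write_cohort_table",
    "write_pattern",
    "read_pattern",
    "write_truth",
    "extract_roi_means",
]

_META_COLS = ("subject_id", "group", "timepoint")


def write_cohort_table(cohort: CohortMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # %.17g is shortest-guaranteed-roundtrip for float64
    cohort.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_cohort_table(
    path: str | Path,
    atlas: RoiAtlas | None = None,
    roi_ids: tuple[str, ...] | None = None,
) -> CohortMatrix:
    """Load and validate a cohort table.

    When an atlas (or explicit ROI ordering) is given, the file must carry
    exactly those ROI columns; any column order is accepted and normalized
    to the canonical order.  Without one, the ROI order is taken from the
    file as-is.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"cohort table {path} lacks column {col!r}")
    file_rois = [c for c in df.columns if c not in _META_COLS]
    expected = list(
        roi_ids if roi_ids is not None else (atlas.labels if atlas else file_rois)
    )
    missing = sorted(set(expected) - set(file_rois))
    extra = sorted(set(file_rois) - set(expected))
    if missing:
        raise ValueError(f"cohort table missing ROI column {missing[0]!r}")
    if extra:
        raise ValueError(f"cohort table has unexpected ROI column {extra[0]!r}")
    sub = df[expected]
    bad = sub.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing activity at row {i}, "
            f"ROI {expected[j]!r}"
        )
    tp = df["timepoint"].fillna("")
    has_tp = bool((tp.astype(str) != "").any())
    return CohortMatrix(
        activities=sub.to_numpy(dtype=float),
        roi_ids=tuple(expected),
        subject_ids=tuple(str(s) for s in df["subject_id"]),
        group_labels=tuple(str(g) for g in df["group"]),
        timepoint_labels=tuple(str(t) for t in tp) if has_tp else None,
    )


def write_pattern(pattern: MetabolicPattern, path: str | Path) -> None:
    payload = {
        "roi_ids": list(pattern.roi_ids),
        "weights": pattern.weights.tolist(),
        "z_weights": pattern.z_weights.tolist(),
        "vaf": pattern.vaf,
        "group_mean_profile": pattern.group_mean_profile.tolist(),
        "derivation_scores": pattern.derivation_scores.tolist(),
        "orientation": pattern.orientation,
        "derivation_subject_ids": list(pattern.derivation_subject_ids),
        "derivation_group_labels": list(pattern.derivation_group_labels),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_pattern(path: str | Path) -> MetabolicPattern:
    d = json.loads(Path(path).read_text())
    return MetabolicPattern(
        weights=np.asarray(d["weights"]),
        z_weights=np.asarray(d["z_weights"]),
        vaf=float(d["vaf"]),
        group_mean_profile=np.asarray(d["group_mean_profile"]),
        derivation_scores=np.asarray(d["derivation_scores"]),
        orientation=int(d["orientation"]),
        roi_ids=tuple(d["roi_ids"]),
        derivation_subject_ids=tuple(d.get("derivation_subject_ids", ())),
        derivation_group_labels=tuple(d.get("derivation_group_labels", ())),
    )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "planted_weights": truth.planted_weights.tolist(),
        "planted_scores": truth.planted_scores.tolist(),
        "baseline_profile": truth.baseline_profile.tolist(),
        "salient_positive": list(truth.salient_positive),
        "salient_negative": list(truth.salient_negative),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def extract_roi_means(image, label_volume, atlas: RoiAtlas) -> np.ndarray:
    """Mean voxel intensity per atlas ROI from a NIfTI image + label volume.

    ``image`` and ``label_volume`` are nibabel images (or paths) on the
    same voxel grid; voxels labeled 0 are background.  Every atlas index
    must be present in the label volume.  Normalization to the global mean
    is deliberately *not* applied here — that happens in SSM preprocessing.
    """
    import nibabel as nib

    if isinstance(image, (str, Path)):
        image = nib.load(str(image))
    if isinstance(label_volume, (str, Path)):
        label_volume = nib.load(str(label_volume))
    data = np.asanyarray(image.dataobj, dtype=float)
    labels = np.asanyarray(label_volume.dataobj)
    labels = np.rint(labels).astype(int)
    if data.shape != labels.shape:
        raise ValueError(
            f"image grid {data.shape} does not match label grid {labels.shape}"
        )
    out = np.empty(len(atlas))
    for k, (idx, name) in enumerate(zip(atlas.indices, atlas.labels)):
        mask = labels == idx
        if not mask.any():
            raise ValueError(f"atlas label {idx} ({name}) absent from volume")
        out[k] = data[mask].mean()
    return out
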