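"""Region-of-interest atlas handling.

The default atlas has 95 ordered regions: the 90 cortical/subcortical
regions of the automated anatomical labeling (AAL) parcellation plus five
posterior-fossa regions (left/right cerebellar hemispheres, vermis,
left/right pons).  Every other component of the package takes its ROI
ordering from a :class:`RoiAtlas`; the shipped table's numbering is
authoritative for this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = ["RoiAtlas", "default_atlas", "N_DEFAULT_ROIS"]

N_DEFAULT_ROIS = 95


@dataclass(frozen=True)
class RoiAtlas:
    """Ordered ROI parcellation.

    Attributes
    ----------
    indices
        Integer label value of each region (as used in a label volume).
    labels
        Unique region names, in canonical order.
    hemispheres
        One of ``"L"``, ``"R"``, ``"M"`` (midline) per region.
    """

    indices: tuple[int, ...]
    labels: tuple[str, ...]
    hemispheres: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas labels must be unique")
        if len(self.indices) != len(self.labels):
            raise ValueError("indices and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_rois(self) -> int:
        return len(self.labels)

    def label_to_index(self) -> dict[str, int]:
        return dict(zip(self.labels, self.indices))


def default_atlas() -> RoiAtlas:
    """Load the packaged 95-region atlas (90 AAL + cerebellum/vermis/pons)."""
    with resources.files("pdrpnet.data").joinpath("atlas95.tsv").open() as fh:
        tab = pd.read_csv(fh, sep="\t")
    atlas = RoiAtlas(
        indices=tuple(int(i) for i in tab["index"]),
        labels=tuple(tab["label"]),
        hemispheres=tuple(tab["hemisphere"]),
    )
    assert len(atlas) == N_DEFAULT_ROIS
    return atlas
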