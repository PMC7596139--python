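"""Permutation inference on network properties and edge-wise comparisons.

Group differences in C, L or S are tested by relabeling subjects from the
pooled sample (group sizes preserved) and recomputing the full pipeline —
correlation matrix, sparsity thresholding, graph metric — for every
relabeling.  Two-sided p-values use the add-one Monte-Carlo correction;
an exhaustive mode enumerates all balanced relabelings exactly for small
cohorts.  Edge-wise connection differences are tested on the signed
correlations with Fisher's r-to-z transform and Benjamini-Hochberg FDR
control across the edges of the node set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortMatrix
from .connectome import (
    characteristic_path_length,
    clustering_coefficient,
    network_properties,
    threshold_adjacency,
)
from .ssm import SubspacePartition

__all__ = [
    "PermutationResult",
    "EdgeComparisonResult",
    "permutation_metric_test",
    "group_subspace_interaction",
    "edgewise_comparison",
]

_METRICS = ("C", "L", "S")


@dataclass
class PermutationResult:
    """Observed statistic, permutation null, and two-sided p-value."""

    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    sparsity: float
    metric: str
    exhaustive: bool = False


@dataclass
class EdgeComparisonResult:
    """Edge-wise Fisher r-to-z comparison with FDR-adjusted significance."""

    table: pd.DataFrame  # node_i, node_j, r_a, r_b, z, p_raw, p_adj, significant
    fdr_q: float

    @property
    def significant_edges(self) -> list[tuple[str, str]]:
        sig = self.table[self.table["significant"]]
        return list(zip(sig["node_i"], sig["node_j"]))


def _metric_from_rows(
    rows: np.ndarray,
    sparsity: float,
    metric: str,
    n_rand: int,
    seed: int,
) -> float:
    """corr -> threshold -> metric on a subjects x nodes activity block."""
    sds = rows.std(axis=0)
    if np.any(sds == 0):  # degenerate under relabeling; treat as no signal
        corr = np.zeros((rows.shape[1], rows.shape[1]))
        nz = sds > 0
        if nz.sum() >= 2:
            sub = np.abs(np.corrcoef(rows[:, nz].T))
            np.fill_diagonal(sub, 0.0)
            corr[np.ix_(nz, nz)] = sub
    else:
        corr = np.abs(np.corrcoef(rows.T))
        np.fill_diagonal(corr, 0.0)
    adj = threshold_adjacency(corr, sparsity)
    # only the requested metric is computed; permutation loops call this
    # thousands of times
    if metric == "C":
        return clustering_coefficient(adj)
    if metric == "L":
        return characteristic_path_length(adj)[0]
    gm = network_properties(adj, sparsity=sparsity, n_rand=n_rand, seed=seed)
    return getattr(gm, metric)


def _node_block(
    cohort: CohortMatrix, node_set: tuple[str, ...] | None
) -> np.ndarray:
    if node_set is None:
        return cohort.activities
    pos = {r: j for j, r in enumerate(cohort.roi_ids)}
    missing = [r for r in node_set if r not in pos]
    if missing:
        raise ValueError(f"node_set ROI {missing[0]!r} not in cohort")
    return cohort.activities[:, [pos[r] for r in node_set]]


def _check_groups(
    cohort_a: CohortMatrix, cohort_b: CohortMatrix, min_subjects: int
) -> None:
    if cohort_a.n_subjects < min_subjects or cohort_b.n_subjects < min_subjects:
        raise ValueError(
            f"both groups need >= {min_subjects} subjects; got "
            f"{cohort_a.n_subjects} and {cohort_b.n_subjects}"
        )
    if cohort_a.roi_ids != cohort_b.roi_ids:
        raise ValueError("groups must share the same ROI ordering")


def _permutation_test(
    pooled: np.ndarray,
    n_a: int,
    statistic,
    n_perm: int,
    seed: int,
    exhaustive: bool,
) -> tuple[float, np.ndarray, float, bool]:
    n = pooled.shape[0]
    idx_all = np.arange(n)
    observed = statistic(idx_all[:n_a], idx_all[n_a:])
    if exhaustive or (n_perm >= comb(n, n_a)):
        null = np.asarray(
            [
                statistic(np.asarray(c), np.setdiff1d(idx_all, c))
                for c in combinations(range(n), n_a)
            ]
        )
        p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
        return observed, null, p, True
    rng = np.random.default_rng([seed, n, n_a])
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = statistic(perm[:n_a], perm[n_a:])
    p = float(
        (np.sum(np.abs(null) >= abs(observed) - 1e-12) + 1) / (n_perm + 1)
    )
    return observed, null, p, False


def permutation_metric_test(
    cohort_a: CohortMatrix,
    cohort_b: CohortMatrix,
    node_set: tuple[str, ...] | None,
    sparsity: float,
    metric: str = "C",
    n_perm: int = 1000,
    seed: int = 0,
    n_rand: int = 100,
    min_subjects: int = 4,
    exhaustive: bool = False,
) -> PermutationResult:
    """Test ``metric(A) - metric(B)`` against a label-shuffling null.

    Each null draw relabels subjects from the pooled sample preserving
    group sizes and recomputes the metric through the full pipeline.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    _check_groups(cohort_a, cohort_b, min_subjects)
    block_a = _node_block(cohort_a, node_set)
    block_b = _node_block(cohort_b, node_set)
    pooled = np.vstack([block_a, block_b])
    n_a = block_a.shape[0]

    def statistic(ia, ib):
        return _metric_from_rows(
            pooled[ia], sparsity, metric, n_rand, seed
        ) - _metric_from_rows(pooled[ib], sparsity, metric, n_rand, seed)

    observed, null, p, was_exhaustive = _permutation_test(
        pooled, n_a, statistic, n_perm, seed, exhaustive
    )
    return PermutationResult(
        observed=observed,
        null_values=null,
        p_value=p,
        n_perm=len(null),
        seed=seed,
        sparsity=sparsity,
        metric=metric,
        exhaustive=was_exhaustive,
    )


def group_subspace_interaction(
    cohort_a: CohortMatrix,
    cohort_b: CohortMatrix,
    partition: SubspacePartition,
    sparsity: float,
    metric: str = "C",
    n_perm: int = 1000,
    seed: int = 0,
    n_rand: int = 100,
    min_subjects: int = 4,
    exhaustive: bool = False,
) -> PermutationResult:
    """Group x subspace interaction on a network metric.

    The statistic is the difference-of-differences
    ``[m(A, disease) - m(A, non)] - [m(B, disease) - m(B, non)]`` with the
    same subject-relabeling null as :func:`permutation_metric_test`.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    _check_groups(cohort_a, cohort_b, min_subjects)
    dis = _node_block(cohort_a, partition.disease_rois)  # validates labels
    del dis
    blocks = {
        "dis": (
            _node_block(cohort_a, partition.disease_rois),
            _node_block(cohort_b, partition.disease_rois),
        ),
        "non": (
            _node_block(cohort_a, partition.non_subspace_rois),
            _node_block(cohort_b, partition.non_subspace_rois),
        ),
    }
    pooled = {k: np.vstack(v) for k, v in blocks.items()}
    n_a = cohort_a.n_subjects

    def statistic(ia, ib):
        def contrast(idx):
            return _metric_from_rows(
                pooled["dis"][idx], sparsity, metric, n_rand, seed
            ) - _metric_from_rows(
                pooled["non"][idx], sparsity, metric, n_rand, seed
            )

        return contrast(ia) - contrast(ib)

    observed, null, p, was_exhaustive = _permutation_test(
        pooled["dis"], n_a, statistic, n_perm, seed, exhaustive
    )
    return PermutationResult(
        observed=observed,
        null_values=null,
        p_value=p,
        n_perm=len(null),
        seed=seed,
        sparsity=sparsity,
        metric=f"{metric}_interaction",
        exhaustive=was_exhaustive,
    )


def edgewise_comparison(
    cohort_a: CohortMatrix,
    cohort_b: CohortMatrix,
    node_set: tuple[str, ...] | None = None,
    fdr_q: float = 0.05,
    min_subjects: int = 4,
) -> EdgeComparisonResult:
    """Compare every pairwise connection between two groups.

    Signed Pearson correlations are Fisher r-to-z transformed; the
    difference statistic ``(z_a - z_b) / sqrt(1/(n_a-3) + 1/(n_b-3))`` is
    referred to the standard normal (two-sided), and Benjamini-Hochberg
    adjustment across all edges of the node set controls the FDR.
    """
    _check_groups(cohort_a, cohort_b, min_subjects)
    n_a, n_b = cohort_a.n_subjects, cohort_b.n_subjects
    if n_a <= 3 or n_b <= 3:
        raise ValueError("Fisher r-to-z comparison needs > 3 subjects per group")
    block_a = _node_block(cohort_a, node_set)
    block_b = _node_block(cohort_b, node_set)
    labels = node_set if node_set is not None else cohort_a.roi_ids
    r_a = np.corrcoef(block_a.T)
    r_b = np.corrcoef(block_b.T)
    iu, ju = np.triu_indices(len(labels), k=1)

    clip = 1 - 1e-12
    za = np.arctanh(np.clip(r_a[iu, ju], -clip, clip))
    zb = np.arctanh(np.clip(r_b[iu, ju], -clip, clip))
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    z = (za - zb) / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    reject, p_adj, _, _ = multipletests(p_raw, alpha=fdr_q, method="fdr_bh")

    table = pd.DataFrame(
        {
            "node_i": [labels[i] for i in iu],
            "node_j": [labels[j] for j in ju],
            "r_a": r_a[iu, ju],
            "r_b": r_b[iu, ju],
            "z": z,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": reject,
        }
    )
    return EdgeComparisonResult(table=table, fdr_q=fdr_q)
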