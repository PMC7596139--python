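"""Group-level metabolic correlation networks and small-world properties.

Within each group, the covariance of regional metabolic activity across
subjects defines a network: nodes are ROIs, edge strength is the absolute
Pearson correlation between the two regions' activities over subjects.
Binary undirected graphs are obtained by keeping the strongest edges up to
a sparsity threshold (fraction of possible edges), and characterized by

* ``C`` — mean nodal clustering coefficient (network segregation),
* ``L`` — characteristic path length, the mean shortest-path length over
  node pairs (network integration),
* ``S`` — small-worldness, ``(C/L)`` relative to the mean ``C/L`` of
  uniform random graphs with the same node and edge counts.

All computations are on dense numpy adjacency matrices with shortest paths
from :mod:`scipy.sparse.csgraph`; the random-graph null is an ensemble of
seeded uniform G(n, m) graphs, cached per (n, m, n_rand, seed) so sweeps
and permutation loops do not recompute it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .cohort import CohortMatrix

__all__ = [
    "GraphMetrics",
    "group_correlation_matrix",
    "threshold_adjacency",
    "min_full_connectivity_sparsity",
    "clustering_coefficient",
    "characteristic_path_length",
    "network_properties",
    "sparsity_sweep",
    "DEFAULT_SWEEP_GRID",
]

#: Sweep range over which all groups' networks stay fully connected.
DEFAULT_SWEEP_GRID = tuple(round(0.25 + 0.01 * k, 2) for k in range(26))


@dataclass
class GraphMetrics:
    """Small-world summary of one binary graph at one sparsity."""

    C: float
    L: float
    S: float
    C_rand: float
    L_rand: float
    sparsity: float
    connected: bool
    n_nodes: int
    n_edges: int
    n_rand: int
    seed: int


def group_correlation_matrix(
    cohort: CohortMatrix,
    node_set: tuple[str, ...] | None = None,
    min_subjects: int = 4,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Absolute Pearson correlation matrix of ROI activities across subjects.

    Returns the symmetric ``|r|`` matrix with a zero diagonal and the node
    labels in matrix order.  ``node_set`` restricts to an ROI subset (e.g.
    the disease subspace); order follows ``node_set`` when given.
    """
    if cohort.n_subjects < min_subjects:
        raise ValueError(
            f"need >= {min_subjects} subjects for a stable correlation "
            f"matrix, got {cohort.n_subjects}"
        )
    if node_set is None:
        labels = cohort.roi_ids
        data = cohort.activities
    else:
        pos = {r: j for j, r in enumerate(cohort.roi_ids)}
        missing = [r for r in node_set if r not in pos]
        if missing:
            raise ValueError(f"node_set ROI {missing[0]!r} not in cohort")
        labels = tuple(node_set)
        data = cohort.activities[:, [pos[r] for r in node_set]]
    sds = data.std(axis=0)
    if np.any(sds == 0):
        bad = labels[int(np.argmax(sds == 0))]
        raise ValueError(f"ROI {bad!r} has zero variance across subjects")
    corr = np.corrcoef(data.T)
    corr_abs = np.abs(corr)
    np.clip(corr_abs, 0.0, 1.0, out=corr_abs)
    np.fill_diagonal(corr_abs, 0.0)
    return corr_abs, labels


def _ranked_edges(corr_abs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending weight, ties by (i, j)."""
    n = corr_abs.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = corr_abs[iu, ju]
    # lexsort: last key primary -> sort by -w, then i, then j
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def threshold_adjacency(corr_abs: np.ndarray, sparsity: float) -> np.ndarray:
    """Binarize by keeping the ``floor(sparsity * n(n-1)/2)`` strongest edges.

    Ties at the cutoff are broken deterministically by ascending (i, j)
    node order, so repeated calls give identical graphs.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    corr_abs = np.asarray(corr_abs, dtype=float)
    n = corr_abs.shape[0]
    if corr_abs.shape != (n, n):
        raise ValueError("corr_abs must be square")
    k = math.floor(sparsity * n * (n - 1) / 2)
    if k == 0:
        raise ValueError(
            f"sparsity {sparsity} yields zero edges on {n} nodes"
        )
    iu, ju = _ranked_edges(corr_abs)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[:k], ju[:k]] = 1
    adj[ju[:k], iu[:k]] = 1
    return adj


def _is_connected(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return n_comp == 1


def min_full_connectivity_sparsity(
    corr_abs: np.ndarray,
    grid: tuple[float, ...] | None = None,
) -> float | None:
    """Smallest grid sparsity (default 1%..50% by 1%) giving one component.

    Returns the sparsity as a percentage, or ``None`` if the network is not
    fully connected anywhere on the grid (a reported outcome, not an error).
    """
    if grid is None:
        grid = tuple(round(0.01 * k, 2) for k in range(1, 51))
    n = corr_abs.shape[0]
    for s in grid:
        if math.floor(s * n * (n - 1) / 2) == 0:
            continue
        if _is_connected(threshold_adjacency(corr_abs, s)):
            return round(100.0 * s, 10)
    return None


def clustering_coefficient(adj: np.ndarray) -> float:
    """Mean nodal clustering coefficient; nodes of degree < 2 contribute 0."""
    a = np.asarray(adj, dtype=float)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return float(c.mean())


def characteristic_path_length(adj: np.ndarray) -> tuple[float, bool]:
    """Mean shortest-path length over node pairs (arithmetic mean).

    Disconnected graphs are scored on their largest connected component and
    flagged ``connected=False``.
    """
    a = csr_matrix(np.asarray(adj))
    n = a.shape[0]
    if n < 2:
        raise ValueError("need >= 2 nodes for a path length")
    n_comp, labels = connected_components(a, directed=False)
    connected = n_comp == 1
    if not connected:
        sizes = np.bincount(labels)
        keep = np.flatnonzero(labels == int(np.argmax(sizes)))
        if keep.size < 2:
            return float("nan"), False
        a = csr_matrix(np.asarray(adj)[np.ix_(keep, keep)])
        n = keep.size
    d = shortest_path(a, method="D", directed=False, unweighted=True)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean()), connected


_RAND_CACHE: dict[tuple[int, int, int, int], tuple[float, float]] = {}


def _random_reference(
    n: int, m: int, n_rand: int, seed: int
) -> tuple[float, float]:
    """Mean C and L of seeded uniform G(n, m) random graphs (memoized)."""
    key = (n, m, n_rand, seed)
    if key in _RAND_CACHE:
        return _RAND_CACHE[key]
    rng = np.random.default_rng([seed, n, m, n_rand])
    iu, ju = np.triu_indices(n, k=1)
    n_possible = iu.size
    cs, ls = [], []
    for _ in range(n_rand):
        pick = rng.choice(n_possible, size=m, replace=False)
        adj = np.zeros((n, n), dtype=np.int8)
        adj[iu[pick], ju[pick]] = 1
        adj[ju[pick], iu[pick]] = 1
        cs.append(clustering_coefficient(adj))
        ls.append(characteristic_path_length(adj)[0])
    out = (float(np.mean(cs)), float(np.nanmean(ls)))
    _RAND_CACHE[key] = out
    return out


def network_properties(
    adjacency: np.ndarray,
    sparsity: float | None = None,
    n_rand: int = 100,
    seed: int = 0,
) -> GraphMetrics:
    """Compute C, L and small-worldness S of one binary graph.

    ``S = (C/L) / (C_rand/L_rand)`` with the random reference the mean over
    ``n_rand`` uniform random graphs with identical node and edge counts.
    """
    adj = np.asarray(adjacency)
    n = adj.shape[0]
    m = int(adj.sum()) // 2
    if n == 0 or m == 0:
        raise ValueError("empty graph: no nodes or no edges")
    c = clustering_coefficient(adj)
    length, connected = characteristic_path_length(adj)
    c_rand, l_rand = _random_reference(n, m, n_rand, seed)
    if c_rand > 0 and l_rand > 0 and length > 0:
        s = (c / length) / (c_rand / l_rand)
    else:
        s = float("nan")
    if sparsity is None:
        sparsity = m / (n * (n - 1) / 2)
    return GraphMetrics(
        C=c,
        L=length,
        S=s,
        C_rand=c_rand,
        L_rand=l_rand,
        sparsity=float(sparsity),
        connected=connected,
        n_nodes=n,
        n_edges=m,
        n_rand=n_rand,
        seed=seed,
    )


def sparsity_sweep(
    cohort: CohortMatrix,
    node_set: tuple[str, ...] | None = None,
    grid: tuple[float, ...] = DEFAULT_SWEEP_GRID,
    n_rand: int = 100,
    seed: int = 0,
    min_subjects: int = 4,
) -> list[GraphMetrics]:
    """Network properties of one group's network across a sparsity grid."""
    corr_abs, _ = group_correlation_matrix(
        cohort, node_set, min_subjects=min_subjects
    )
    out = []
    for s in grid:
        adj = threshold_adjacency(corr_abs, s)
        out.append(network_properties(adj, sparsity=s, n_rand=n_rand, seed=seed))
    return out
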