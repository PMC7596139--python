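"""Correlation networks, sparsity thresholding, and small-world metrics.

Graph metrics are checked against two independent routes: explicit
brute-force triangle enumeration / all-pairs breadth-first search written
here, and networkx.
"""

import math
from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from pdrpnet.cohort import CohortMatrix
from pdrpnet.connectome import (
    DEFAULT_SWEEP_GRID,
    characteristic_path_length,
    clustering_coefficient,
    group_correlation_matrix,
    min_full_connectivity_sparsity,
    network_properties,
    sparsity_sweep,
    threshold_adjacency,
)
from pdrpnet.simulate import SimulationConfig, simulate_cohort
from conftest import make_toy_cohort


# ---------------------------------------------------------------- oracles
def brute_clustering(adj):
    n = adj.shape[0]
    cs = []
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            1 for a, b in combinations(nbrs, 2) if adj[a, b]
        )
        cs.append(links / (k * (k - 1) / 2))
    return sum(cs) / n


def brute_path_length(adj):
    """All-pairs BFS mean distance on the largest component."""
    n = adj.shape[0]

    def bfs(src, nodes):
        dist = {src: 0}
        q = deque([src])
        while q:
            v = q.popleft()
            for u in nodes:
                if adj[v, u] and u not in dist:
                    dist[u] = dist[v] + 1
                    q.append(u)
        return dist

    comps = []
    seen = set()
    for v in range(n):
        if v not in seen:
            comp = set(bfs(v, range(n)))
            comps.append(sorted(comp))
            seen |= comp
    comp = max(comps, key=len)
    total, count = 0, 0
    for i, src in enumerate(comp):
        d = bfs(src, comp)
        for dst in comp[i + 1 :]:
            total += d[dst]
            count += 1
    return total / count, len(comps) == 1


def random_adjacency(n, m, seed):
    g = nx.gnm_random_graph(n, m, seed=seed)
    return nx.to_numpy_array(g, dtype=int)


# ------------------------------------------------------------- correlation
class TestGroupCorrelation:
    def test_identical_columns_correlate_to_one(self):
        r = np.random.default_rng(0)
        base = np.exp(r.normal(0, 0.2, 6))
        act = np.column_stack([base, base, np.exp(r.normal(0, 0.2, 6))])
        cohort = CohortMatrix(
            activities=act,
            roi_ids=("a", "b", "c"),
            subject_ids=tuple(f"s{i}" for i in range(6)),
            group_labels=("HC",) * 6,
        )
        corr, labels = group_correlation_matrix(cohort)
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert corr[0, 0] == 0.0

    def test_anticorrelated_columns_correlate_to_one_in_absolute_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        act = np.column_stack([x, 10.0 - x, x**2])
        cohort = CohortMatrix(
            activities=act,
            roi_ids=("a", "b", "c"),
            subject_ids=tuple(f"s{i}" for i in range(5)),
            group_labels=("PD",) * 5,
        )
        corr, _ = group_correlation_matrix(cohort)
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_pairwise_pearson_oracle(self):
        cohort = make_toy_cohort(5, 4, seed=2)
        corr, _ = group_correlation_matrix(cohort)
        for i in range(4):
            for j in range(i + 1, 4):
                r, _p = stats.pearsonr(
                    cohort.activities[:, i], cohort.activities[:, j]
                )
                assert corr[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_too_few_subjects_rejected(self):
        cohort = make_toy_cohort(3, 5)
        with pytest.raises(ValueError, match=">= 4 subjects"):
            group_correlation_matrix(cohort)

    def test_zero_variance_roi_named(self):
        act = np.exp(np.random.default_rng(0).normal(0, 0.2, (5, 3)))
        act[:, 1] = 2.5
        cohort = CohortMatrix(
            activities=act,
            roi_ids=("a", "flat", "c"),
            subject_ids=tuple(f"s{i}" for i in range(5)),
            group_labels=("HC",) * 5,
        )
        with pytest.raises(ValueError, match="flat"):
            group_correlation_matrix(cohort)

    def test_node_subset_follows_requested_order(self):
        cohort = make_toy_cohort(6, 5, seed=1)
        corr, labels = group_correlation_matrix(cohort, ("R3", "R0", "R4"))
        assert labels == ("R3", "R0", "R4")
        full, _ = group_correlation_matrix(cohort)
        assert corr[0, 1] == pytest.approx(full[0, 3], abs=1e-12)


# ------------------------------------------------------------ thresholding
class TestThresholdAdjacency:
    def test_edge_count_formula_at_quarter_sparsity(self, rng):
        corr = np.abs(rng.normal(0, 1, (95, 95)))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 0)
        adj = threshold_adjacency(corr, 0.25)
        assert adj.sum() // 2 == 1116  # floor(0.25 * 95 * 94 / 2)

    def test_full_sparsity_gives_complete_graph(self, rng):
        corr = np.abs(rng.normal(0, 1, (10, 10)))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 0)
        adj = threshold_adjacency(corr, 1.0)
        assert adj.sum() == 10 * 9

    def test_tie_break_is_deterministic_and_lexicographic(self):
        n = 5
        corr = np.full((n, n), 0.5)
        np.fill_diagonal(corr, 0)
        adj1 = threshold_adjacency(corr, 0.3)  # 3 of 10 tied edges
        adj2 = threshold_adjacency(corr, 0.3)
        np.testing.assert_array_equal(adj1, adj2)
        # lexicographically first pairs win: (0,1), (0,2), (0,3)
        assert adj1[0, 1] and adj1[0, 2] and adj1[0, 3]
        assert adj1.sum() // 2 == 3

    def test_zero_edge_sparsity_rejected(self):
        corr = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="zero edges"):
            threshold_adjacency(corr, 0.01)

    def test_symmetry_and_zero_diagonal(self, rng):
        corr = np.abs(rng.normal(0, 1, (12, 12)))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 0)
        adj = threshold_adjacency(corr, 0.4)
        np.testing.assert_array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 0)


# ----------------------------------------------------- minimum connectivity
def spanning_tree_matrix(n=95, seed=0):
    """|r| matrix whose n-1 strongest edges form a random spanning tree."""
    r = np.random.default_rng(seed)
    corr = r.uniform(0.0, 0.5, (n, n))
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 0)
    perm = r.permutation(n)
    for a, b in zip(perm[:-1], perm[1:]):
        corr[a, b] = corr[b, a] = r.uniform(0.9, 1.0)
    return corr


class TestMinFullConnectivity:
    def test_spanning_tree_fixture_connects_at_three_percent(self):
        corr = spanning_tree_matrix()
        # 94 tree edges: floor(0.02*4465)=89 < 94 <= floor(0.03*4465)=133
        assert min_full_connectivity_sparsity(corr) == pytest.approx(3.0)
        # independent connectivity check at the reported threshold
        adj = threshold_adjacency(corr, 0.03)
        assert nx.is_connected(nx.from_numpy_array(adj))
        adj_below = threshold_adjacency(corr, 0.02)
        assert not nx.is_connected(nx.from_numpy_array(adj_below))

    def test_isolating_a_node_raises_minimum_sparsity(self):
        corr = spanning_tree_matrix()
        weak = corr.copy()
        # node 7 loses its strong tree edges; its best edge now ranks
        # below ~10% of the background, so it joins the graph much later
        weak[7, :] = weak[:, 7] = 0.45
        np.fill_diagonal(weak, 0)
        s = min_full_connectivity_sparsity(weak)
        assert s is not None and s > 3.0

    def test_result_stays_on_grid(self, rng):
        corr = np.abs(rng.normal(0, 0.5, (20, 20)))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 0)
        s = min_full_connectivity_sparsity(corr)
        if s is not None:
            assert 1.0 <= s <= 50.0

    def test_never_connectable_reports_failure(self):
        # one all-but-isolated node: its strongest edge still ranks below
        # the grid's edge budget at 50%
        n = 30
        corr = np.zeros((n, n))
        sub = slice(0, n - 1)
        block = np.random.default_rng(3).uniform(0.5, 1.0, (n - 1, n - 1))
        corr[sub, sub] = (block + block.T) / 2
        np.fill_diagonal(corr, 0)
        corr[n - 1, :] = corr[:, n - 1] = 1e-6
        corr[n - 1, n - 1] = 0
        # at 50% sparsity, floor(0.5*435)=217 of 435 edges; the 29 edges of
        # the last node are the 29 weakest so it stays isolated
        assert min_full_connectivity_sparsity(corr) is None


# ------------------------------------------------------------ graph metrics
class TestNetworkProperties:
    def test_complete_graph_closed_form(self):
        for n in (3, 5, 9):
            adj = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
            gm = network_properties(adj, n_rand=5, seed=0)
            assert gm.C == pytest.approx(1.0, abs=1e-12)
            assert gm.L == pytest.approx(1.0, abs=1e-12)
            assert gm.connected

    def test_ring_lattice_matches_brute_force_and_networkx(self):
        g = nx.watts_strogatz_graph(20, 4, 0.0, seed=1)  # ring, 2 per side
        adj = nx.to_numpy_array(g, dtype=int)
        gm = network_properties(adj, n_rand=5, seed=0)
        c_brute = brute_clustering(adj)
        l_brute, conn = brute_path_length(adj)
        assert gm.C == pytest.approx(c_brute, abs=1e-12)
        assert gm.L == pytest.approx(l_brute, abs=1e-12)
        assert gm.C == pytest.approx(nx.average_clustering(g), abs=1e-12)
        assert gm.L == pytest.approx(
            nx.average_shortest_path_length(g), abs=1e-12
        )

    @pytest.mark.parametrize("n,m,seed", [
        (8, 10, 0), (15, 25, 1), (30, 60, 2), (30, 200, 3), (12, 12, 4),
    ])
    def test_random_graphs_match_brute_force(self, n, m, seed):
        adj = random_adjacency(n, m, seed)
        gm = network_properties(adj, n_rand=3, seed=0)
        c_brute = brute_clustering(adj)
        l_brute, connected = brute_path_length(adj)
        assert gm.C == pytest.approx(c_brute, abs=1e-12)
        assert gm.L == pytest.approx(l_brute, abs=1e-12)
        assert gm.connected == connected

    def test_small_worldness_of_random_graph_is_near_one(self):
        adj = random_adjacency(30, 130, seed=5)
        gm = network_properties(adj, n_rand=100, seed=3)
        assert gm.S == pytest.approx(1.0, abs=0.15)

    def test_metrics_invariant_under_node_relabeling(self, rng):
        adj = random_adjacency(18, 40, seed=6)
        perm = rng.permutation(18)
        gm1 = network_properties(adj, n_rand=10, seed=0)
        gm2 = network_properties(adj[np.ix_(perm, perm)], n_rand=10, seed=0)
        assert gm1.C == pytest.approx(gm2.C, abs=1e-12)
        assert gm1.L == pytest.approx(gm2.L, abs=1e-12)
        assert gm1.S == pytest.approx(gm2.S, abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            network_properties(np.zeros((4, 4)))

    def test_random_reference_reproducible(self):
        adj = random_adjacency(16, 40, seed=7)
        gm1 = network_properties(adj, n_rand=20, seed=9)
        gm2 = network_properties(adj, n_rand=20, seed=9)
        assert gm1.C_rand == gm2.C_rand
        assert gm1.L_rand == gm2.L_rand


# ------------------------------------------------------------------- sweep
class TestSparsitySweep:
    def test_grid_size_and_monotone_edges(self):
        cohort = make_toy_cohort(10, 20, seed=4)
        metrics = sparsity_sweep(cohort, None, n_rand=3, seed=0)
        assert len(metrics) == 26
        edges = [m.n_edges for m in metrics]
        assert edges == sorted(edges)
        for m in metrics:
            assert m.n_edges == math.floor(m.sparsity * 20 * 19 / 2)

    def test_default_grid_covers_quarter_to_half(self):
        assert DEFAULT_SWEEP_GRID[0] == 0.25
        assert DEFAULT_SWEEP_GRID[-1] == 0.50
        assert len(DEFAULT_SWEEP_GRID) == 26

    def test_pd_subspace_clustering_exceeds_hc_at_quarter_sparsity(self):
        # planted subspace-factor difference: same direction as the
        # reported patient-vs-control clustering contrast
        cfg = SimulationConfig(
            n_hc=30,
            n_pd=30,
            score_sd=0.05,
            score_mean_pd=0.5,
            noise_sd=0.3,
            subject_scale_sd=0.05,
            subspace_factor_loading_hc=0.0,
            subspace_factor_loading_pd=0.9,
            seed=2,
        )
        cohort, truth = simulate_cohort(cfg)
        nodes = tuple(cohort.roi_ids[j] for j in truth.salient_all)
        gm_pd = sparsity_sweep(
            cohort.subset_group("PD"), nodes, grid=(0.25,), seed=0
        )[0]
        gm_hc = sparsity_sweep(
            cohort.subset_group("HC"), nodes, grid=(0.25,), seed=0
        )[0]
        assert gm_pd.C > gm_hc.C
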