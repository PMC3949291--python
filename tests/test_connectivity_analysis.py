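"""NCN similarity, affinity propagation, cluster statistics, event spread."""

import numpy as np
import pytest

import l5sim
from l5sim.connectivity_analysis import (ClusterResult, gini_coefficient,
                                         undirected_adjacency)


def brute_force_ncn(adj):
    """Independent oracle: explicit common-neighbour set intersection."""
    und = (adj | adj.T).astype(bool)
    np.fill_diagonal(und, False)
    n = adj.shape[0]
    nbrs = [set(np.flatnonzero(und[i])) for i in range(n)]
    s = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j:
                s[i, j] = len((nbrs[i] & nbrs[j]) - {i, j})
    return s


class TestNcnSimilarity:
    def test_five_node_toy_graph(self):
        # edges {1-3, 2-3, 1-4, 2-4, 1-5} (0-indexed below): nodes 1 and 2
        # share exactly the two common neighbours 3 and 4
        adj = np.zeros((5, 5), dtype=bool)
        for a, b in [(0, 2), (1, 2), (0, 3), (1, 3), (0, 4)]:
            adj[a, b] = True
        s = l5sim.ncn_similarity(adj)
        assert s[0, 1] == 2
        assert np.array_equal(s, brute_force_ncn(adj))

    def test_isolated_pair_zero(self):
        adj = np.zeros((4, 4), dtype=bool)
        assert l5sim.ncn_similarity(adj)[0, 1] == 0

    def test_identical_neighborhoods(self):
        adj = np.zeros((7, 7), dtype=bool)
        adj[0, 2:] = True
        adj[1, 2:] = True
        assert l5sim.ncn_similarity(adj)[0, 1] == 5

    def test_matches_brute_force_on_random_digraphs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            adj = rng.random((15, 15)) < 0.3
            np.fill_diagonal(adj, False)
            assert np.array_equal(l5sim.ncn_similarity(adj), brute_force_ncn(adj))

    def test_symmetric_and_degree_bounded(self):
        rng = np.random.default_rng(1)
        adj = rng.random((30, 30)) < 0.2
        np.fill_diagonal(adj, False)
        s = l5sim.ncn_similarity(adj)
        assert np.array_equal(s, s.T)
        deg = undirected_adjacency(adj).sum(1)
        bound = np.minimum(deg[:, None], deg[None, :])
        off = ~np.eye(30, dtype=bool)
        assert np.all(s[off] <= bound[off])


class TestAffinityPropagation:
    def test_recovers_two_disjoint_cliques(self):
        k = 6
        adj = np.zeros((2 * k, 2 * k), dtype=bool)
        adj[:k, :k] = True
        adj[k:, k:] = True
        np.fill_diagonal(adj, False)
        s = l5sim.ncn_similarity(adj)
        result = l5sim.ap_cluster(s, preference=2.0, seed=0)
        assert result.n_clusters == 2
        assert len(set(result.labels[:k])) == 1
        assert len(set(result.labels[k:])) == 1
        assert result.labels[0] != result.labels[k]

    def test_partition_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(2)
        adj = rng.random((60, 60)) < 0.2
        np.fill_diagonal(adj, False)
        s = l5sim.ncn_similarity(adj)
        result = l5sim.ap_cluster(s.astype(float), seed=0)
        assert result.labels.shape == (60,)
        assert np.all(result.labels >= 0)
        for k_, ex in enumerate(result.exemplars):
            assert result.labels[ex] == k_

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        adj = rng.random((50, 50)) < 0.25
        np.fill_diagonal(adj, False)
        s = l5sim.ncn_similarity(adj).astype(float)
        a = l5sim.ap_cluster(s, seed=7)
        b = l5sim.ap_cluster(s, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_asymmetric_similarity_rejected(self):
        s = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError):
            l5sim.ap_cluster(s)


class TestClusterStats:
    def test_complete_digraph_cluster_has_full_inner_ratio(self):
        n = 6
        w = np.full((n, n), 5.0)
        np.fill_diagonal(w, 0.0)
        positions = np.random.default_rng(0).uniform(0, 100, (n, 3))
        clusters = ClusterResult(exemplars=np.array([0]),
                                 labels=np.zeros(n, dtype=int))
        stats = l5sim.cluster_stats(clusters, w, positions)
        assert stats.mean_inner_ratio_pct == pytest.approx(100.0)
        assert stats.mean_inner_strength == pytest.approx(5.0)
        assert stats.n_outer_synapses == 0

    def test_synapse_totals_conserved(self, standard_run):
        w = standard_run.weights_final
        s = l5sim.ncn_similarity(w > 0)
        clusters = l5sim.ap_cluster(s.astype(float), seed=0)
        stats = l5sim.cluster_stats(clusters, w, standard_run.geometry.positions)
        assert stats.n_inner_synapses + stats.n_outer_synapses == \
            int(np.count_nonzero(w))


class TestNcnRule:
    def test_flat_on_erdos_renyi_null(self):
        # i.i.d. weights cannot depend on NCN: strength curve flat within noise
        rng = np.random.default_rng(4)
        n = 300
        adj = rng.random((n, n)) < 0.1
        np.fill_diagonal(adj, False)
        w = np.where(adj, rng.uniform(1, 4, (n, n)), 0.0)
        table = l5sim.ncn_rule(adj, w)
        busy = table[table.n_pairs > 200]
        strengths = busy.mean_strength_mv.dropna()
        assert strengths.size >= 3
        assert strengths.std() < 0.25
        assert (table.n_pairs > 0).all()  # empty bins omitted

    def test_evolved_network_curves_rise_with_ncn(self, standard_run):
        w = standard_run.weights_final
        table = l5sim.ncn_rule(w > 0, w)
        busy = table[table.n_pairs > 300]
        # connection probability increases over the populated NCN range
        ncn = busy.ncn.to_numpy()
        p = busy.p_connect.to_numpy()
        lo = p[ncn <= np.percentile(ncn, 30)].mean()
        hi = p[ncn >= np.percentile(ncn, 70)].mean()
        assert hi > lo


class TestStdpSpread:
    def test_gini_zero_for_uniform(self):
        assert gini_coefficient(np.full(100, 7.0)) == pytest.approx(0.0, abs=1e-9)

    def test_gini_near_one_for_degenerate(self):
        x = np.zeros(1000)
        x[0] = 1.0
        assert gini_coefficient(x) > 0.99

    def test_spread_metrics_on_counts(self):
        rng = np.random.default_rng(5)
        positions = rng.uniform(0, 300, (50, 3))
        counts = np.zeros((50, 50), dtype=int)
        counts[0, 1] = 100
        mask = counts >= 0
        np.fill_diagonal(mask, False)
        spread = l5sim.stdp_event_spread(counts, positions, synapse_mask=mask)
        assert spread.gini > 0.99
        assert spread.top_region_fraction == pytest.approx(1.0)
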