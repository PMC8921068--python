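"""Directed modularity, Louvain, permutation significance, VI, hubs, Ward trees."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from hmgm import (
    OccupancyTable,
    community_zscore,
    directed_modularity,
    generate_planted_partition_graph,
    louvain,
    modularity_significance,
    select_hubs,
    select_resolution_vi,
    variation_of_information,
    ward_cluster_occupancy,
)
from hmgm.community import Partition, linkage_to_newick


def all_partitions(n):
    """Every set partition of range(n) as a label vector (Bell-number many)."""
    if n == 1:
        yield [0]
        return
    for rest in all_partitions(n - 1):
        k = max(rest) + 1
        for c in range(k + 1):
            yield rest + [c]


def noisy_nested_graph(seed, n_blocks=4, bs=5, p_fine=0.95, p_mid=0.5, p_out=0.05):
    """Two-scale planted structure: 4 fine blocks grouped into 2 superblocks."""
    n = n_blocks * bs
    rng = np.random.default_rng(seed)
    fine = np.repeat(np.arange(n_blocks), bs)
    coarse = fine // 2
    prob = np.where(
        fine[:, None] == fine[None, :], p_fine,
        np.where(coarse[:, None] == coarse[None, :], p_mid, p_out),
    )
    W = (rng.random((n, n)) < prob) * (0.5 + rng.random((n, n)))
    W = np.triu(W, 1)
    return W + W.T, fine, coarse


class TestDirectedModularity:
    def test_all_in_one_partition_is_exactly_zero(self, rng):
        W = rng.random((7, 7))
        assert directed_modularity(W, np.zeros(7, dtype=int), gamma=1.0) == 0.0

    def test_two_directed_cycles(self):
        # two disconnected 2-cycles, unit weights: Q = 1 - 8/16 = 0.5
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        assert directed_modularity(W, [0, 0, 1, 1]) == pytest.approx(0.5, abs=1e-15)

    def test_singleton_partition_is_negative_without_self_loops(self, rng):
        W = rng.random((5, 5))
        np.fill_diagonal(W, 0.0)
        q = directed_modularity(W, np.arange(5))
        m = W.sum()
        expected = -np.sum(W.sum(axis=1) * W.sum(axis=0)) / m**2
        assert q == pytest.approx(expected, abs=1e-12)
        assert q < 0

    def test_matches_undirected_modularity_on_symmetric_graphs(self, rng):
        import networkx as nx

        for _ in range(5):
            W = rng.random((8, 8))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            labels = rng.integers(0, 3, size=8)
            G = nx.from_numpy_array(W)
            comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
            q_nx = nx.community.modularity(G, comms, weight="weight")
            assert directed_modularity(W, labels) == pytest.approx(q_nx, abs=1e-10)

    def test_zero_graph_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            directed_modularity(np.zeros((3, 3)), [0, 1, 2])


class TestLouvain:
    def test_disconnected_cliques_recovered_exactly(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 1.0
        W[4:, 4:] = 1.0
        np.fill_diagonal(W, 0.0)
        for seed in range(5):
            p = louvain(W, seed=seed, n_runs=3)
            assert adjusted_rand_score([0] * 4 + [1] * 4, p.labels) == 1.0

    def test_planted_partition_recovery(self):
        hits = 0
        for seed in range(20):
            W, labels = generate_planted_partition_graph([10, 10], 0.9, 0.05, seed=seed)
            p = louvain(W, seed=seed, n_runs=5)
            hits += adjusted_rand_score(labels, p.labels) >= 0.9
        assert hits >= 18

    def test_structureless_graph_gives_near_zero_ari(self):
        aris = []
        for seed in range(20):
            W, labels = generate_planted_partition_graph([10, 10], 0.5, 0.5, seed=100 + seed)
            p = louvain(W, seed=seed, n_runs=5)
            aris.append(adjusted_rand_score(labels, p.labels))
        assert abs(np.mean(aris)) < 0.2

    def test_near_optimal_against_exhaustive_enumeration(self, rng):
        # brute-force Bell-number oracle on small symmetric weighted graphs
        for trial in range(4):
            n = 6 + (trial % 2)
            M = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
            W = np.triu(M, 1)
            W = W + W.T
            if W.sum() == 0:
                continue
            q_best = max(directed_modularity(W, labs) for labs in all_partitions(n))
            p = louvain(W, seed=trial, n_runs=10)
            assert p.Q >= 0.95 * q_best - 1e-12

    def test_deterministic_given_seed(self, rng):
        W, _ = generate_planted_partition_graph([6, 6], 0.8, 0.1, seed=3)
        p1 = louvain(W, seed=42, n_runs=4)
        p2 = louvain(W, seed=42, n_runs=4)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.Q == p2.Q


class TestModularitySignificance:
    def test_planted_structure_is_significant(self):
        W, labels = generate_planted_partition_graph([10, 10], 0.9, 0.05, seed=0)
        part = Partition(labels=labels + 1, gamma=1.0, Q=directed_modularity(W, labels))
        assert modularity_significance(W, part, n_perm=10_000, seed=0) <= 1e-3

    def test_null_graphs_behave_as_null(self):
        calm = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            W = (rng.random((20, 20)) < 0.3) * 1.0
            np.fill_diagonal(W, 0.0)
            labels = np.repeat([1, 2], 10)
            part = Partition(labels=labels, gamma=1.0, Q=directed_modularity(W, labels - 1))
            p = modularity_significance(W, part, n_perm=200, seed=seed)
            calm += p > 0.05
        assert calm >= 17

    def test_complete_uniform_graph_gives_p_one(self):
        W = np.ones((8, 8)) - np.eye(8)
        part = Partition(labels=np.repeat([1, 2], 4), gamma=1.0, Q=0.0)
        assert modularity_significance(W, part, n_perm=500, seed=0) == 1.0

    def test_single_community_untestable(self, rng):
        W = rng.random((5, 5))
        part = Partition(labels=np.ones(5, dtype=int), gamma=1.0, Q=0.0)
        assert modularity_significance(W, part, n_perm=100) == 1.0


class TestVariationOfInformation:
    def test_metric_properties(self, rng):
        n = 30
        a = rng.integers(0, 4, n)
        b = rng.integers(0, 3, n)
        assert variation_of_information(a, a) == 0.0
        assert variation_of_information(a, b) == pytest.approx(
            variation_of_information(b, a), abs=1e-12
        )
        assert variation_of_information(a, b) <= np.log(n) + 1e-12

    def test_stable_graph_returns_smallest_gamma(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 1.0
        W[4:, 4:] = 1.0
        np.fill_diagonal(W, 0.0)
        gamma, vi = select_resolution_vi(W, [0.5, 1.0, 1.5], n_runs=4, seed=0)
        np.testing.assert_allclose(vi, 0.0, atol=1e-12)
        assert gamma == 0.5

    def test_two_scale_graph_selects_a_planted_scale(self):
        hits = 0
        grid = list(np.round(np.arange(0.2, 2.01, 0.2), 2))
        for seed in range(20):
            W, fine, coarse = noisy_nested_graph(seed)
            gamma, _ = select_resolution_vi(W, grid, n_runs=6, seed=seed)
            p = louvain(W, gamma, seed=seed, n_runs=6)
            ari = max(
                adjusted_rand_score(fine, p.labels), adjusted_rand_score(coarse, p.labels)
            )
            hits += ari >= 0.8
        assert hits >= 15


class TestHubs:
    def test_regular_community_all_zero_hub_lowest_index(self):
        W = np.ones((6, 6)) - np.eye(6)
        part = Partition(labels=np.repeat([1, 2], 3), gamma=1.0, Q=0.0)
        z = community_zscore(W, part)
        np.testing.assert_allclose(z, 0.0)
        hubs = select_hubs(z, part)
        assert hubs.hubs == {1: 0, 2: 3}

    def test_star_center_is_hub(self):
        # 5-node star: center 0 connected to leaves 1-4
        W = np.zeros((5, 5))
        W[0, 1:] = 1.0
        W[1:, 0] = 1.0
        part = Partition(labels=np.ones(5, dtype=int), gamma=1.0, Q=0.0)
        z = community_zscore(W, part)
        assert np.argmax(z) == 0
        assert select_hubs(z, part).hubs[1] == 0

    def test_zscores_standardised_within_community(self, rng):
        W = rng.random((12, 12))
        part = Partition(labels=np.repeat([1, 2], 6), gamma=1.0, Q=0.0)
        z = community_zscore(W, part)
        for lab in (1, 2):
            idx = part.members(lab)
            assert z[idx].mean() == pytest.approx(0.0, abs=1e-10)
            assert z[idx].std(ddof=0) == pytest.approx(1.0, abs=1e-10)


class TestWardOccupancy:
    def _table(self, kappa):
        kappa = np.asarray(kappa, dtype=float)
        return OccupancyTable(
            kappa=kappa,
            subject_ids=[f"s{i}" for i in range(kappa.shape[0])],
            n_timepoints=[100] * kappa.shape[0],
        )

    def test_identical_subjects_merge_at_zero_height(self):
        kappa = np.array([[0.7, 0.2, 0.1], [0.7, 0.2, 0.1], [0.1, 0.2, 0.7], [0.2, 0.3, 0.5]])
        Z_sub, _ = ward_cluster_occupancy(self._table(kappa))
        first = Z_sub[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-8)

    def test_block_occupancy_bipartition(self):
        rng = np.random.default_rng(0)
        kappa = np.zeros((6, 4))
        kappa[:3, :2] = rng.dirichlet([5, 5], 3)  # subjects 0-2 live in states 0,1
        kappa[3:, 2:] = rng.dirichlet([5, 5], 3)  # subjects 3-5 live in states 2,3
        Z_sub, _ = ward_cluster_occupancy(self._table(kappa))
        from scipy.cluster.hierarchy import fcluster

        cut = fcluster(Z_sub, 2, criterion="maxclust")
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], cut) == 1.0

    def test_linkage_heights_monotone(self, rng):
        kappa = rng.dirichlet(np.ones(5), size=8)
        Z_sub, Z_state = ward_cluster_occupancy(self._table(kappa))
        for Z in (Z_sub, Z_state):
            assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_newick_export_parseable(self, rng):
        import dendropy

        kappa = rng.dirichlet(np.ones(4), size=5)
        Z_sub, _ = ward_cluster_occupancy(self._table(kappa))
        nwk = linkage_to_newick(Z_sub, [f"s{i}" for i in range(5)])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 5

    def test_zero_variance_row_named(self):
        kappa = np.array([[0.25, 0.25, 0.25, 0.25], [0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]])
        with pytest.raises(ValueError, match="subject row"):
            ward_cluster_occupancy(self._table(kappa))
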