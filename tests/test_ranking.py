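"""Functional homogeneity, random-walk null sampling and T-score ranking."""

import numpy as np
import pytest

from hmgm import (
    MultiplexModel,
    functional_homogeneity,
    markov_information_graph,
    rank_communities,
    sample_null_communities,
    t_score,
)
from hmgm.community import Partition

from conftest import planted_multiplex, random_multiplex, random_psd


class TestFunctionalHomogeneity:
    def test_zero_mean_community(self):
        assert functional_homogeneity(np.zeros(5), np.eye(5), [0, 1, 2]) == 0.0

    def test_scalar_quadratic_form(self):
        mu = np.array([0.0, 2.0, 0.0])
        sigma = np.diag([1.0, 3.0, 1.0])
        assert functional_homogeneity(mu, sigma, [1]) == pytest.approx(12.0)

    def test_pair_community_double_sum(self):
        mu = np.array([1.0, 1.0])
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert functional_homogeneity(mu, sigma, [0, 1]) == pytest.approx(3.0)

    def test_matches_explicit_double_sum_oracle(self, rng):
        # FH computed by the matrix quadratic form vs element-by-element sum
        for _ in range(50):
            D = int(rng.integers(3, 10))
            mu = rng.standard_normal(D)
            sigma = random_psd(rng, D)
            size = int(rng.integers(1, D + 1))
            C = rng.choice(D, size=size, replace=False)
            brute = sum(mu[x] * sigma[x, y] * mu[y] for x in C for y in C)
            assert functional_homogeneity(mu, sigma, C) == pytest.approx(brute, abs=1e-10)

    def test_nonnegative_for_psd_sigma(self, rng):
        for _ in range(20):
            mu = rng.standard_normal(6)
            sigma = random_psd(rng, 6)
            assert functional_homogeneity(mu, sigma, [0, 2, 4]) >= -1e-12

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            functional_homogeneity(np.ones(3), np.eye(3), [])


class TestNullSampler:
    def test_single_state_full_size_walk_covers_graph(self, rng):
        D = 6
        S = random_psd(rng, D)
        g = markov_information_graph(rng.standard_normal(D), S)
        model = MultiplexModel([g], np.eye(1), np.array([1.0]), sigmas=S[None])
        sample = sample_null_communities(model, size=D, start_pool=range(D), L=20, seed=0)
        for _, C in sample.pairs:
            assert set(C) == set(range(D))

    def test_size_one_is_uniform_over_start_pool(self):
        model = random_multiplex(K=2, D=8, seed=3)
        pool = [1, 4, 6]
        sample = sample_null_communities(model, size=1, start_pool=pool, L=3000, seed=0)
        counts = {p: 0 for p in pool}
        for _, C in sample.pairs:
            counts[int(C[0])] += 1
        for p in pool:
            assert counts[p] / 3000 == pytest.approx(1 / 3, abs=0.05)

    def test_walk_rarely_escapes_isolated_block(self, rng):
        # two-block covariance with 1e-6 inter-block correlation
        D = 10
        S = np.eye(D)
        S[:5, :5] += 0.5 - 0.5 * np.eye(5)
        S[5:, 5:] += 0.5 - 0.5 * np.eye(5)
        S[:5, 5:] = 1e-6
        S[5:, :5] = 1e-6
        g = markov_information_graph(rng.standard_normal(D), S)
        model = MultiplexModel([g], np.eye(1), np.array([1.0]), sigmas=S[None])
        sample = sample_null_communities(model, size=3, start_pool=[0, 1, 2], L=10_000, seed=1)
        inside = sum(1 for _, C in sample.pairs if set(C) <= set(range(5)))
        assert inside / 10_000 >= 0.99

    def test_oversized_request_rejected(self):
        model = random_multiplex(K=2, D=5)
        with pytest.raises(ValueError, match="size"):
            sample_null_communities(model, size=6, start_pool=[0], L=10)

    def test_deterministic_given_seed(self):
        model = random_multiplex(K=3, D=8, seed=1)
        s1 = sample_null_communities(model, 3, [0, 1], L=50, seed=9)
        s2 = sample_null_communities(model, 3, [0, 1], L=50, seed=9)
        for (a_s, a_c), (b_s, b_c) in zip(s1.pairs, s2.pairs):
            assert a_s == b_s
            np.testing.assert_array_equal(a_c, b_c)


class TestTScore:
    def test_single_state_whole_graph_scores_zero(self, rng):
        D = 5
        S = random_psd(rng, D)
        g = markov_information_graph(rng.standard_normal(D), S)
        model = MultiplexModel([g], np.eye(1), np.array([1.0]), sigmas=S[None])
        t, _ = t_score(model, 0, list(range(D)), L=200, seed=0)
        assert t == 0.0

    def test_planted_coherent_community_scores_high(self):
        model, C = planted_multiplex()
        t, sign = t_score(model, 0, C, L=10_000, seed=0)
        assert t >= 0.95
        assert sign == 1

    def test_self_sampled_communities_average_half(self):
        model = random_multiplex(K=5, D=12, seed=7)
        null = sample_null_communities(model, 4, list(range(12)), L=30, seed=1)
        ts = [
            t_score(model, s_l, C_l, L=1000, seed=100 + i)[0]
            for i, (s_l, C_l) in enumerate(null.pairs)
        ]
        assert np.mean(ts) == pytest.approx(0.5, abs=0.1)

    def test_monte_carlo_spread_within_binomial_bound(self):
        model, C = planted_multiplex()
        L = 1000
        ts = [t_score(model, 0, C, L=L, seed=s)[0] for s in range(12)]
        assert np.std(ts) <= 1.0 / (2.0 * np.sqrt(L))

    def test_invariant_to_region_relabelling(self):
        model, C = planted_multiplex(seed=11)
        t_orig, _ = t_score(model, 0, C, L=2000, seed=0)
        perm = np.roll(np.arange(12), 5)
        graphs, sigmas = [], []
        for g in model.state_graphs:
            S = model.sigmas[g.state_id][np.ix_(perm, perm)]
            graphs.append(markov_information_graph(g.a[perm], S, state_id=g.state_id))
            sigmas.append(S)
        model_p = MultiplexModel(graphs, model.P, model.pi, sigmas=np.stack(sigmas))
        C_p = [int(np.flatnonzero(perm == c)[0]) for c in C]
        t_perm, _ = t_score(model_p, 0, C_p, L=2000, seed=0)
        assert t_perm == pytest.approx(t_orig, abs=3.0 / (2 * np.sqrt(2000)) + 0.02)


class TestRankCommunities:
    def test_single_community_gets_rank_one(self):
        model = random_multiplex(K=2, D=6, seed=5)
        part = Partition(labels=np.ones(6, dtype=int), gamma=1.0, Q=0.0)
        ranked = rank_communities(model, 0, part, L=200, seed=0)
        assert len(ranked) == 1
        assert ranked[0].rank == 1

    def test_planted_community_ranked_first(self):
        hits = 0
        for seed in range(20):
            model, C = planted_multiplex(seed=seed)
            labels = np.zeros(12, dtype=int)
            labels[list(C)] = 1
            labels[4:8][labels[4:8] == 0] = 2
            labels[8:] = 3
            part = Partition(labels=labels + 1, gamma=1.0, Q=0.0)
            ranked = rank_communities(model, 0, part, L=400, seed=seed)
            top = ranked[0]
            hits += set(top.members) == set(C)
        assert hits >= 18

    def test_bit_exact_reproducibility(self):
        model, C = planted_multiplex()
        part = Partition(labels=np.repeat([1, 2, 3], 4), gamma=1.0, Q=0.0)
        r1 = rank_communities(model, 0, part, L=500, seed=4)
        r2 = rank_communities(model, 0, part, L=500, seed=4)
        assert [(r.community_id, r.t_score, r.fh) for r in r1] == [
            (r.community_id, r.t_score, r.fh) for r in r2
        ]
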