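"""Direct cePathway screening: theta, the running-sum score, permutation test."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from macpath.direct_cepathway import (
    compute_ces,
    compute_theta,
    enumerate_pairs,
    permutation_pvalue,
    screen_all_pairs,
)
from macpath.io_formats import PathwayCollection

from conftest import random_network


def ces_prefix_oracle(sublist, Q):
    """Brute-force: evaluate the running sum at every prefix independently."""
    q_set = set(Q)
    weights = [abs(t) for _, t in sublist]
    hits = [g in q_set for g, _ in sublist]
    n, n_h = len(sublist), sum(hits)
    if n == 0 or n_h == 0:
        return 0.0
    n_r = sum(w for w, h in zip(weights, hits) if h)
    best = 0.0
    running = 0.0
    for w, h in zip(weights, hits):
        running += (w / n_r) if h else (-1.0 / (n - n_h))
        best = max(best, running)
    return best


def random_sublist(rng, n):
    thetas = -rng.uniform(0.01, 2.0, size=n)
    genes = [f"g{i}" for i in range(n)]
    return list(zip(genes, np.sort(thetas)))


class TestTheta:
    def test_single_edge_goes_to_loss_list(self):
        net = random_network(np.random.default_rng(0), 0)
        net.add_edge("a", "y", rho_normal=0.7, rho_tumor=0.2,
                     overlap_k=6, overlap_p=1e-5, overlap_q=1e-4)
        ranking = compute_theta(net, {"a"})
        assert ranking.loss == [("y", pytest.approx(-0.5))]
        assert ranking.gain == []

    def test_theta_adds_over_pathway_members(self):
        net = random_network(np.random.default_rng(0), 0)
        net.add_edge("a", "y", rho_normal=0.1, rho_tumor=0.4,
                     overlap_k=6, overlap_p=1e-5, overlap_q=1e-4)
        net.add_edge("b", "y", rho_normal=0.2, rho_tumor=0.4,
                     overlap_k=6, overlap_p=1e-5, overlap_q=1e-4)
        ranking = compute_theta(net, {"a", "b"})
        assert ranking.gain == [("y", pytest.approx(0.5))]

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            net = random_network(rng, 20, edge_prob=0.25)
            members = {f"g{i}" for i in rng.choice(20, size=5, replace=False)}
            ranking = compute_theta(net, members, include_members=True)
            got = {g: t for g, t in ranking.loss + ranking.gain}
            # oracle: direct sum over the adjacency list
            expected = {}
            for y in net.nodes:
                s = sum(
                    net.delta_rho(x, y) for x in members if net.has_edge(x, y)
                )
                if s != 0:
                    expected[y] = s
            assert set(got) == set(expected)
            for g in got:
                assert got[g] == pytest.approx(expected[g], abs=1e-12)

    def test_own_members_excluded_by_default(self):
        net = random_network(np.random.default_rng(0), 0)
        net.add_edge("a", "b", rho_normal=0.9, rho_tumor=0.1,
                     overlap_k=6, overlap_p=1e-5, overlap_q=1e-4)
        net.add_edge("a", "y", rho_normal=0.9, rho_tumor=0.1,
                     overlap_k=6, overlap_p=1e-5, overlap_q=1e-4)
        ranking = compute_theta(net, {"a", "b"})
        assert [g for g, _ in ranking.loss] == ["y"]
        kept = compute_theta(net, {"a", "b"}, include_members=True)
        assert {g for g, _ in kept.loss} == {"y", "a", "b"}

    def test_disjoint_pathway_yields_empty_ranking(self):
        net = random_network(np.random.default_rng(1), 10, edge_prob=0.3)
        ranking = compute_theta(net, {"absent1", "absent2"})
        assert ranking.is_empty


class TestCes:
    def test_single_top_hit_scores_one(self):
        sublist = [("a", -1.0), ("b", -0.5), ("c", -0.4), ("d", -0.1)]
        assert compute_ces(sublist, {"a"}) == pytest.approx(1.0)

    def test_disjoint_query_scores_zero(self):
        sublist = [("a", -1.0), ("b", -0.5)]
        assert compute_ces(sublist, {"zz"}) == 0.0

    def test_equals_prefix_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 51))
            sublist = random_sublist(rng, n)
            q = {g for g, _ in sublist if rng.random() < 0.3}
            q |= {"decoy"}
            assert compute_ces(sublist, q) == pytest.approx(
                ces_prefix_oracle(sublist, q), abs=1e-12
            )

    def test_one_iff_all_hits_precede_all_misses(self):
        sublist = random_sublist(np.random.default_rng(3), 12)
        genes = [g for g, _ in sublist]
        assert compute_ces(sublist, set(genes[:4])) == pytest.approx(1.0)
        assert compute_ces(sublist, set(genes[:3] + genes[5:6])) < 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.integers(min_value=2, max_value=30),
        st.floats(min_value=0.1, max_value=100.0),
        st.integers(min_value=0, max_value=2**31),
    )
    def test_invariant_to_positive_scaling_of_theta(self, n, scale, seed):
        rng = np.random.default_rng(seed)
        sublist = random_sublist(rng, n)
        q = {g for g, _ in sublist if rng.random() < 0.4}
        scaled = [(g, t * scale) for g, t in sublist]
        assert compute_ces(scaled, q) == pytest.approx(compute_ces(sublist, q))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            sublist = random_sublist(rng, int(rng.integers(1, 40)))
            q = {g for g, _ in sublist if rng.random() < 0.5}
            ces = compute_ces(sublist, q)
            assert 0.0 <= ces <= 1.0 + 1e-12


class TestPermutationPvalue:
    def test_query_equal_to_sublist_gives_p_one(self):
        sublist = random_sublist(np.random.default_rng(0), 10)
        ces, p = permutation_pvalue(sublist, {g for g, _ in sublist}, n_perm=50, seed=1)
        assert p == 1.0

    def test_no_hits_returns_sentinel(self):
        sublist = random_sublist(np.random.default_rng(0), 10)
        ces, p = permutation_pvalue(sublist, {"zz"}, n_perm=50, seed=1)
        assert ces == 0.0 and np.isnan(p)

    def test_top_loaded_query_is_significant(self):
        # all hits in the top decile of a 200-gene list
        rng = np.random.default_rng(8)
        sublist = random_sublist(rng, 200)
        q = {g for g, _ in sublist[:20]}
        ces, p = permutation_pvalue(sublist, q, n_perm=2000, seed=2)
        assert p <= 0.01

    def test_null_pvalues_are_uniform(self):
        # KS test of uniformity over replicated random query placements
        rng = np.random.default_rng(9)
        sublist = random_sublist(rng, 40)
        genes = [g for g, _ in sublist]
        pvals = []
        for r in range(500):
            q = set(rng.choice(genes, size=10, replace=False))
            _, p = permutation_pvalue(sublist, q, n_perm=200, seed=rng)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_reproducible_for_fixed_seed(self):
        sublist = random_sublist(np.random.default_rng(1), 60)
        q = {g for g, _ in sublist[::4]}
        r1 = permutation_pvalue(sublist, q, n_perm=500, seed=33)
        r2 = permutation_pvalue(sublist, q, n_perm=500, seed=33)
        assert r1 == r2


class TestScreen:
    def test_disjoint_pathways_produce_no_tests(self):
        net = random_network(np.random.default_rng(0), 10, edge_prob=0.4)
        pathways = PathwayCollection(
            {"P1": frozenset({"h1", "h2"}), "P2": frozenset({"h3", "h4"})}
        )
        calls = screen_all_pairs(net, pathways, "loss", n_perm=50, seed=0, return_all=True)
        assert calls == []

    def test_pair_enumeration_count(self):
        pathways = PathwayCollection(
            {f"P{i}": frozenset({f"x{i}"}) for i in range(40)}
        )
        assert sum(1 for _ in enumerate_pairs(pathways)) == 40 * 39 // 2

    def test_planted_pair_is_the_only_call(self, planted_study):
        from macpath.cerna_network import build_network

        spec, (expr, mirna, targets, pathways, truth) = planted_study
        net, _ = build_network(expr, mirna, targets)
        calls = screen_all_pairs(net, pathways, "loss", n_perm=500, seed=4)
        assert len(calls) >= 1
        top = {calls[0].pathway_P, calls[0].pathway_Q}
        planted = truth.planted_pairs[0]
        assert top == {planted["pathway_P"], planted["pathway_Q"]}
        called_pairs = {frozenset((c.pathway_P, c.pathway_Q)) for c in calls}
        assert called_pairs == {frozenset(top)}
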