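"""Minimum mediator sets: cover construction, exact solvers, enrichment."""

from __future__ import annotations

import numpy as np
import pytest

from macpath.mediators import (
    CoverInstance,
    aggregate_minimal_mediators,
    build_cover_instance,
    enumerate_min_covers,
    mediator_enrichment,
    solve_min_cover,
)
from macpath.indirect_cepathway import ChainEvidence, KappaRanking


def make_ranking(name, chains):
    loss = []
    return KappaRanking(pathway_P=name, loss=loss, gain=[], chains=chains)


def random_instance(rng, n_mediators, n_universe):
    universe = [f"u{i}" for i in range(n_universe)]
    cover = {}
    for m in range(n_mediators):
        size = int(rng.integers(1, n_universe + 1))
        cover[f"m{m}"] = frozenset(rng.choice(universe, size=size, replace=False))
    covered = frozenset().union(*cover.values())
    return CoverInstance(universe=covered, cover_sets=cover)


class TestCoverInstance:
    def test_single_chain(self):
        rank_p = make_ranking(
            "P", {"z": {"x": ChainEvidence(delta_xz=-0.3, mediators=frozenset({"y"}))}}
        )
        rank_q = make_ranking("Q", {})
        inst = build_cover_instance(rank_p, rank_q, P={"x"}, Q={"z"})
        assert inst.universe == frozenset({"x", "z"})
        assert inst.cover_sets == {"y": frozenset({"x", "z"})}

    def test_shared_mediator_covers_all_four_endpoints(self):
        rank_p = make_ranking(
            "P",
            {
                "z1": {"x1": ChainEvidence(-0.3, frozenset({"y"}))},
                "z2": {"x2": ChainEvidence(-0.2, frozenset({"y"}))},
            },
        )
        rank_q = make_ranking("Q", {})
        inst = build_cover_instance(rank_p, rank_q, P={"x1", "x2"}, Q={"z1", "z2"})
        assert inst.cover_sets["y"] == frozenset({"x1", "x2", "z1", "z2"})

    def test_pathway_members_are_not_admissible_mediators(self):
        rank_p = make_ranking(
            "P",
            {
                "z": {
                    "x": ChainEvidence(-0.3, frozenset({"x2"})),  # mediator inside P
                }
            },
        )
        rank_q = make_ranking("Q", {})
        with pytest.raises(ValueError, match="no mediated relationships"):
            build_cover_instance(rank_p, rank_q, P={"x", "x2"}, Q={"z"})

    def test_direction_filter_drops_wrong_sign_chains(self):
        rank_p = make_ranking(
            "P",
            {
                "z1": {"x": ChainEvidence(-0.3, frozenset({"y1"}))},
                "z2": {"x": ChainEvidence(+0.4, frozenset({"y2"}))},
            },
        )
        rank_q = make_ranking("Q", {})
        inst = build_cover_instance(rank_p, rank_q, P={"x"}, Q={"z1", "z2"}, direction="loss")
        assert "y2" not in inst.cover_sets
        assert inst.universe == frozenset({"x", "z1"})


class TestSolvers:
    def test_textbook_instance_has_optimum_two(self):
        inst = CoverInstance(
            universe=frozenset("1234"),
            cover_sets={
                "m1": frozenset("12"),
                "m2": frozenset("34"),
                "m3": frozenset("123"),
            },
        )
        for solver in ("exact-ilp", "branch-and-bound"):
            assert len(solve_min_cover(inst, solver=solver)) == 2

    def test_single_covering_mediator(self):
        inst = CoverInstance(
            universe=frozenset("abc"),
            cover_sets={"big": frozenset("abc"), "small": frozenset("a")},
        )
        assert solve_min_cover(inst) == frozenset({"big"})

    def test_degenerate_tie_any_single_mediator(self):
        inst = CoverInstance(
            universe=frozenset({"u"}),
            cover_sets={f"m{i}": frozenset({"u"}) for i in range(5)},
        )
        sol = solve_min_cover(inst, solver="branch-and-bound", seed=3)
        assert len(sol) == 1

    @pytest.mark.parametrize("solver", ["exact-ilp", "branch-and-bound"])
    def test_matches_exhaustive_minimum_on_random_instances(self, solver):
        rng = np.random.default_rng(17)
        for _ in range(40):
            inst = random_instance(rng, n_mediators=int(rng.integers(2, 11)),
                                   n_universe=int(rng.integers(2, 9)))
            optimum = len(enumerate_min_covers(inst)[0])
            assert len(solve_min_cover(inst, solver=solver, seed=rng)) == optimum


class TestAggregation:
    def symmetric_instance(self):
        return CoverInstance(
            universe=frozenset("1234"),
            cover_sets={
                "m1": frozenset("12"),
                "m2": frozenset("34"),
                "m3": frozenset("123"),
            },
        )

    def test_union_over_trials_finds_all_optimal_solutions(self):
        inst = self.symmetric_instance()
        result = aggregate_minimal_mediators(inst, n_perm=200, seed=0)
        oracle_union = frozenset().union(*enumerate_min_covers(inst))
        assert result.union_minimal == oracle_union == frozenset({"m1", "m2", "m3"})
        assert result.optimum_size == 2
        assert all(len(s) == 2 for s in result.solutions)

    def test_unique_optimum_is_stable(self):
        inst = CoverInstance(
            universe=frozenset("ab"),
            cover_sets={"m1": frozenset("ab"), "m2": frozenset("a")},
        )
        result = aggregate_minimal_mediators(inst, n_perm=50, seed=1)
        assert result.union_minimal == frozenset({"m1"})
        assert result.other_mediators == frozenset({"m2"})

    def test_single_trial_returns_single_solution(self):
        result = aggregate_minimal_mediators(self.symmetric_instance(), n_perm=1, seed=2)
        assert len(result.solutions) == 1
        assert result.union_minimal == result.solutions[0]

    def test_union_bounded_by_true_union_and_monotone(self):
        inst = self.symmetric_instance()
        oracle_union = frozenset().union(*enumerate_min_covers(inst))
        prev = frozenset()
        for n_perm in (1, 5, 50):
            union = aggregate_minimal_mediators(inst, n_perm=n_perm, seed=7).union_minimal
            assert prev <= union <= oracle_union
            prev = union


class TestEnrichment:
    def test_reference_equals_background(self):
        bg = {f"g{i}" for i in range(30)}
        obs, mean, sd, p = mediator_enrichment(
            set(list(bg)[:10]), bg, bg, n_trials=50, seed=0
        )
        assert obs == 1.0 and mean == 1.0 and sd == 0.0 and p == 1.0

    def test_disjoint_reference_gives_p_near_one(self):
        bg = [f"g{i}" for i in range(100)]
        mediators = set(bg[:10])
        reference = set(bg[50:90])
        obs, mean, sd, p = mediator_enrichment(mediators, reference, bg, n_trials=200, seed=1)
        assert obs == 0.0
        assert p > 0.9

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(12)
        bg = [f"g{i}" for i in range(400)]
        reference = set(bg[:100])
        detections = 0
        n_reps = 50
        for rep in range(n_reps):
            # mediators sampled with reference genes 3x over-weighted
            w = np.where([g in reference for g in bg], 3.0, 1.0)
            w /= w.sum()
            mediators = set(rng.choice(bg, size=60, replace=False, p=w))
            _, _, _, p = mediator_enrichment(
                mediators, reference, bg, n_trials=100, seed=int(rng.integers(2**31))
            )
            detections += p <= 0.05
        assert detections >= 0.9 * n_reps

    def test_background_must_contain_mediators(self):
        with pytest.raises(ValueError):
            mediator_enrichment({"a"}, {"a"}, {"b"}, n_trials=10, seed=0)
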