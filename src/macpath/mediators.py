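"""Minimum sets of mediating genes for indirect cePathway calls.

For a dysregulated indirect pathway pair (P, Q), every qualifying two-hop
chain x—y—z (x and z pathway genes, y the mediator) contributes cover
evidence: mediator y "covers" the pathway genes it is chained to. Finding
the fewest mediators that cover every involved pathway gene is the
minimum set cover problem, solved exactly here either by integer linear
programming (binary indicator per mediator, covering constraint per
pathway gene) or by a pure-Python branch-and-bound that doubles as an
independent oracle on small instances.

Solvers return one optimum; the set of *all* minimum covers is explored
by re-solving under random permutations of the mediator order (mirroring
how LP solvers pick different vertices of the optimal face under input
permutation) and, for small instances, by exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .indirect_cepathway import KappaRanking

__all__ = [
    "CoverInstance",
    "MinimalMediatorResult",
    "build_cover_instance",
    "solve_min_cover",
    "enumerate_min_covers",
    "aggregate_minimal_mediators",
    "mediator_enrichment",
]


@dataclass
class CoverInstance:
    """A set-cover instance: pathway genes to cover, mediators as sets.

    ``universe`` holds the pathway genes (members of P or Q) that appear as
    an endpoint of at least one qualifying chain and are coverable;
    ``cover_sets`` maps each mediator (never itself a P or Q member) to the
    universe genes it covers. ``uncoverable`` records pathway genes seen in
    chain evidence but covered by no admissible mediator.
    """

    universe: frozenset[str]
    cover_sets: dict[str, frozenset[str]]
    uncoverable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.cover_sets = {m: frozenset(s) & self.universe for m, s in self.cover_sets.items()}
        covered = frozenset().union(*self.cover_sets.values()) if self.cover_sets else frozenset()
        if self.universe - covered:
            raise ValueError(
                f"universe genes not covered by any mediator: {sorted(self.universe - covered)}"
            )

    @property
    def mediators(self) -> list[str]:
        return list(self.cover_sets)


@dataclass
class MinimalMediatorResult:
    """Aggregated minimum covers across randomized solver runs."""

    optimum_size: int
    solutions: list[frozenset[str]]
    union_minimal: frozenset[str]
    other_mediators: frozenset[str]


def build_cover_instance(
    ranking_P: KappaRanking,
    ranking_Q: KappaRanking,
    P: Iterable[str],
    Q: Iterable[str],
    direction: Literal["loss", "gain", None] = None,
) -> CoverInstance:
    """Build the cover instance for pair (P, Q) from both kappa orientations.

    Chains from ranking_P contribute when the far gene z lies in Q (and
    symmetrically for ranking_Q with z in P); each carrying mediator covers
    both chain endpoints. Mediators inside P ∪ Q are not admissible. With
    ``direction`` given, only chains whose delta_rho(x, z) has that sign
    are used. Pathway genes with no admissible mediator are pruned into
    ``uncoverable`` rather than failing the instance.
    """
    p_set, q_set = frozenset(P), frozenset(Q)
    blocked = p_set | q_set
    cover: dict[str, set[str]] = {}
    seen_endpoints: set[str] = set()

    def want(delta: float) -> bool:
        if direction is None:
            return True
        return delta < 0 if direction == "loss" else delta > 0

    for ranking, far_side in ((ranking_P, q_set), (ranking_Q, p_set)):
        for z, per_x in ranking.chains.items():
            if z not in far_side:
                continue
            for x, ev in per_x.items():
                if not want(ev.delta_xz):
                    continue
                seen_endpoints.update((x, z))
                for y in ev.mediators:
                    if y in blocked:
                        continue
                    cover.setdefault(y, set()).update((x, z))

    covered = set().union(*cover.values()) if cover else set()
    universe = seen_endpoints & covered
    uncoverable = seen_endpoints - covered
    if not universe:
        raise ValueError("no mediated relationships for this pathway pair")
    return CoverInstance(
        universe=frozenset(universe),
        cover_sets={m: frozenset(s) for m, s in cover.items()},
        uncoverable=frozenset(uncoverable),
    )


def _greedy_cover(instance: CoverInstance, order: Sequence[str]) -> list[str]:
    uncovered = set(instance.universe)
    chosen: list[str] = []
    while uncovered:
        best = max(order, key=lambda m: (len(instance.cover_sets[m] & uncovered),))
        gain = instance.cover_sets[best] & uncovered
        if not gain:
            raise ValueError("instance not coverable")
        chosen.append(best)
        uncovered -= gain
    return chosen


def _branch_and_bound(instance: CoverInstance, order: Sequence[str]) -> frozenset[str]:
    """Exact minimum cover; which co-optimal cover is found follows ``order``.

    The greedy solution supplies only an upper *bound* on the optimum size,
    never a candidate solution, so that reordering the mediators can steer
    the search to any minimum cover (needed for multi-solution aggregation).
    """
    sets = {m: instance.cover_sets[m] for m in order}
    universe = instance.universe
    covers_of: dict[str, list[str]] = {g: [] for g in universe}
    for m in order:
        for g in sets[m]:
            covers_of[g].append(m)

    upper = len(_greedy_cover(instance, order))
    max_set = max((len(s) for s in sets.values()), default=1)
    best: list[frozenset[str] | None] = [None]

    def recurse(uncovered: frozenset[str], chosen: tuple[str, ...]) -> None:
        if not uncovered:
            if best[0] is None or len(chosen) < len(best[0]):
                best[0] = frozenset(chosen)
            return
        lb = len(chosen) + -(-len(uncovered) // max_set)
        if lb > upper:
            return
        if best[0] is not None and lb >= len(best[0]):
            return
        # branch on the hardest-to-cover element; mediator order breaks ties
        g = min(uncovered, key=lambda e: (len(covers_of[e]), e))
        for m in covers_of[g]:
            if m in chosen:
                continue
            recurse(uncovered - sets[m], chosen + (m,))

    recurse(frozenset(universe), ())
    assert best[0] is not None
    return best[0]


def _milp_cover(instance: CoverInstance, order: Sequence[str]) -> frozenset[str]:
    mediators = list(order)
    universe = sorted(instance.universe)
    n = len(mediators)
    a = np.zeros((len(universe), n))
    for j, m in enumerate(mediators):
        for g in instance.cover_sets[m]:
            a[universe.index(g), j] = 1.0
    res = milp(
        c=np.ones(n),
        constraints=LinearConstraint(a, lb=1, ub=np.inf),
        integrality=np.ones(n),
        bounds=(0, 1),
    )
    if not res.success:  # pragma: no cover - infeasibility excluded by construction
        raise RuntimeError(f"ILP solver failed: {res.message}")
    chosen = frozenset(m for m, v in zip(mediators, res.x) if v > 0.5)
    assert frozenset().union(*(instance.cover_sets[m] for m in chosen)) >= instance.universe
    return chosen


def solve_min_cover(
    instance: CoverInstance,
    solver: Literal["exact-ilp", "branch-and-bound"] = "exact-ilp",
    seed: int | np.random.Generator | None = None,
) -> frozenset[str]:
    """A provably minimum-cardinality mediator set covering the universe.

    ``seed`` permutes the mediator ordering, which selects among co-optimal
    solutions without affecting the optimum size.
    """
    order = [m for m in instance.mediators if instance.cover_sets[m]]
    if seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        order = list(rng.permutation(order))
    if solver == "branch-and-bound":
        solution = _branch_and_bound(instance, order)
    elif solver == "exact-ilp":
        solution = _milp_cover(instance, order)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    covered = frozenset().union(*(instance.cover_sets[m] for m in solution))
    if covered < instance.universe:  # pragma: no cover - defensive
        raise RuntimeError("solver returned a non-covering solution")
    return solution


def enumerate_min_covers(instance: CoverInstance, max_mediators: int = 25) -> list[frozenset[str]]:
    """All minimum covers by exhaustive subset search (small instances only)."""
    mediators = instance.mediators
    if len(mediators) > max_mediators:
        raise ValueError(f"instance too large to enumerate ({len(mediators)} mediators)")
    from itertools import combinations

    for size in range(1, len(mediators) + 1):
        found = [
            frozenset(combo)
            for combo in combinations(mediators, size)
            if frozenset().union(*(instance.cover_sets[m] for m in combo))
            >= instance.universe
        ]
        if found:
            return found
    return []


def aggregate_minimal_mediators(
    instance: CoverInstance,
    n_perm: int = 1000,
    seed: int = 0,
    solver: Literal["exact-ilp", "branch-and-bound"] = "branch-and-bound",
) -> MinimalMediatorResult:
    """Collect distinct minimum covers across randomized solver orderings.

    Every trial must return a cover of the same (optimal) cardinality;
    a larger cover indicates a solver fault and raises. ``union_minimal``
    is the union of all distinct solutions seen, ``other_mediators`` the
    instance mediators appearing in none of them.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    solutions: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    optimum: int | None = None
    for _ in range(n_perm):
        sol = solve_min_cover(instance, solver=solver, seed=rng)
        if optimum is None:
            optimum = len(sol)
        elif len(sol) != optimum:
            raise RuntimeError(
                f"solver returned size {len(sol)} after optimum {optimum}"
            )
        if sol not in seen:
            seen.add(sol)
            solutions.append(sol)
    union = frozenset().union(*solutions)
    others = frozenset(instance.mediators) - union
    return MinimalMediatorResult(
        optimum_size=int(optimum),
        solutions=solutions,
        union_minimal=union,
        other_mediators=others,
    )


def mediator_enrichment(
    mediator_set: Iterable[str],
    reference: Iterable[str],
    background: Iterable[str],
    n_trials: int = 100,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """Fraction of mediators in a reference list vs. size-matched random draws.

    Draws ``n_trials`` random gene sets of the same size from ``background``
    (without replacement within a draw) and reports (observed fraction,
    null mean, null sd, empirical p), with p the fraction of trials whose
    null fraction is >= the observed one.
    """
    mediator_set = sorted(set(mediator_set))
    reference = frozenset(reference)
    background = sorted(set(background))
    k = len(mediator_set)
    if k == 0:
        raise ValueError("mediator set is empty")
    if len(background) < k:
        raise ValueError("background smaller than the mediator set")
    if not set(mediator_set) <= set(background):
        raise ValueError("background must contain the mediator set")
    observed = sum(1 for g in mediator_set if g in reference) / k
    rng = np.random.default_rng(seed)
    ref_mask = np.fromiter((g in reference for g in background), dtype=bool)
    fracs = np.empty(n_trials)
    for t in range(n_trials):
        draw = rng.choice(len(background), size=k, replace=False)
        fracs[t] = ref_mask[draw].mean()
    p = float(np.count_nonzero(fracs >= observed)) / n_trials
    return observed, float(fracs.mean()), float(fracs.std()), p
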