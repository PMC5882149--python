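"""Indirect cePathway screening through mediating ceRNAs.

A pathway member x and a distant gene z are in an *indirect* ceRNA
relationship when some mediator y links them in the change network
((x, y) and (y, z) both edges) and the co-expression changes along
(x, y), (y, z) and (x, z) all point the same way — a loss propagated
through the mediator shows up as loss on all three pairs. kappa_P(z)
sums delta_rho(x, z) over the qualifying x in P. Pairs (x, z) that are
themselves network edges are direct evidence and are excluded, so direct
and indirect calls for the same pathway pair rest on disjoint gene-pair
evidence.

The enrichment walk and permutation test are identical to the direct
screen; significance control uses the ForwardStop ordered-testing rule on
the sorted p-values instead of Benjamini-Hochberg, reflecting the lower
prior confidence in two-hop evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .cerna_network import ChangeNetwork
from .direct_cepathway import (
    CePathwayCall,
    enumerate_pairs,
    pair_seed,
    permutation_pvalue,
)
from .io_formats import ExpressionDataset, PathwayCollection

__all__ = [
    "ChainEvidence",
    "KappaRanking",
    "DeltaRhoCache",
    "compute_kappa",
    "forward_stop",
    "screen_indirect_pairs",
]

Direction = Literal["loss", "gain"]


class DeltaRhoCache:
    """On-demand per-group Pearson correlations for arbitrary gene pairs.

    Expression vectors are standardized once per group; rho(x, z) is then an
    inner product. Genes with zero variance in either group have undefined
    correlation and report ``None``.
    """

    def __init__(self, expr: ExpressionDataset):
        self._index = {g: i for i, g in enumerate(expr.gene_ids)}
        self._z: list[np.ndarray] = []
        self._bad = np.zeros(expr.n_genes, dtype=bool)
        for group in expr.groups:
            cols = expr.sample_indices(group)
            if len(cols) < 3:
                raise ValueError(f"group {group!r} has fewer than 3 samples")
            sub = expr.values[:, cols]
            mu = sub.mean(axis=1, keepdims=True)
            sd = sub.std(axis=1, keepdims=True)
            self._bad |= (sd == 0).ravel()
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (sub - mu) / sd
            z /= np.sqrt(sub.shape[1])
            self._z.append(z)

    def defined(self, gene: str) -> bool:
        i = self._index.get(gene)
        return i is not None and not self._bad[i]

    def delta_rho(self, x: str, z: str) -> float | None:
        i, j = self._index.get(x), self._index.get(z)
        if i is None or j is None or self._bad[i] or self._bad[j]:
            return None
        rho_a = float(self._z[0][i] @ self._z[0][j])
        rho_b = float(self._z[1][i] @ self._z[1][j])
        return rho_b - rho_a


@dataclass(frozen=True)
class ChainEvidence:
    """Qualifying indirect evidence from one pathway member x to gene z."""

    delta_xz: float
    mediators: frozenset[str]


@dataclass
class KappaRanking:
    """Indirect-partner genes of a pathway ranked by kappa, sign-partitioned.

    ``chains[z][x]`` records delta_rho(x, z) and the mediators that carried
    the qualifying chains, for downstream minimum-set-cover analysis.
    """

    pathway_P: str
    loss: list[tuple[str, float]] = field(default_factory=list)
    gain: list[tuple[str, float]] = field(default_factory=list)
    chains: dict[str, dict[str, ChainEvidence]] = field(default_factory=dict)
    n_skipped_zero_variance: int = 0

    def sublist(self, direction: Direction) -> list[tuple[str, float]]:
        return self.loss if direction == "loss" else self.gain


def _sign(v: float) -> int:
    # exact zero is neither gain nor loss and never qualifies
    return 0 if v == 0 else (1 if v > 0 else -1)


def compute_kappa(
    net: ChangeNetwork,
    expr: ExpressionDataset,
    P: Iterable[str],
    name: str = "P",
    cache: DeltaRhoCache | None = None,
) -> KappaRanking:
    """kappa_P(z) = sum of delta_rho(x, z) over x in P with a qualifying chain.

    z ranges over genes two hops from P in the network, excluding P's own
    members and any z directly linked to x. An x contributes once per z,
    regardless of how many mediators carry the chain; all carrying
    mediators are recorded as provenance.
    """
    members = set(P)
    if not members:
        raise ValueError("pathway P is empty")
    if cache is None:
        cache = DeltaRhoCache(expr)
    chains: dict[str, dict[str, ChainEvidence]] = {}
    kappa: dict[str, float] = {}
    skipped: set[str] = set()
    for x in members:
        if x not in net:
            continue
        for y in net.neighbors(x):
            d_xy = net.delta_rho(x, y)
            s_xy = _sign(d_xy)
            if s_xy == 0:
                continue
            for z in net.neighbors(y):
                if z == x or z in members or net.has_edge(x, z):
                    continue
                d_yz = net.delta_rho(y, z)
                if _sign(d_yz) != s_xy:
                    continue
                d_xz = cache.delta_rho(x, z)
                if d_xz is None:
                    skipped.add(z)
                    continue
                if _sign(d_xz) != s_xy:
                    continue
                per_z = chains.setdefault(z, {})
                if x in per_z:
                    per_z[x] = ChainEvidence(
                        delta_xz=per_z[x].delta_xz,
                        mediators=per_z[x].mediators | {y},
                    )
                else:
                    per_z[x] = ChainEvidence(delta_xz=d_xz, mediators=frozenset({y}))
                    kappa[z] = kappa.get(z, 0.0) + d_xz
    loss = sorted(((g, k) for g, k in kappa.items() if k < 0), key=lambda e: (e[1], e[0]))
    gain = sorted(((g, k) for g, k in kappa.items() if k > 0), key=lambda e: (-e[1], e[0]))
    return KappaRanking(
        pathway_P=name,
        loss=loss,
        gain=gain,
        chains=chains,
        n_skipped_zero_variance=len(skipped),
    )


def forward_stop(p_values: Sequence[float], alpha: float) -> int:
    """ForwardStop rule: largest k with (1/k) sum_{i<=k} -log(1 - p_i) <= alpha.

    ``p_values`` must already be sorted ascending (no silent sort: the rule
    is an ordered-testing procedure and the caller owns the ordering).
    Returns the number of rejected hypotheses, 0 when none qualify.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if p.size == 0:
        return 0
    if np.any(np.diff(p) < 0):
        raise ValueError("p-values must be sorted ascending")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    clamped = np.minimum(p, 1 - 1e-15)
    means = np.cumsum(-np.log1p(-clamped)) / np.arange(1, p.size + 1)
    ok = np.nonzero(means <= alpha)[0]
    return int(ok[-1] + 1) if ok.size else 0


def screen_indirect_pairs(
    net: ChangeNetwork,
    expr: ExpressionDataset,
    pathways: PathwayCollection,
    direction: Direction,
    n_perm: int = 2000,
    seed: int = 0,
    alpha: float = 0.01,
    min_Q_overlap: int = 5,
    return_all: bool = False,
) -> tuple[list[CePathwayCall], dict[str, KappaRanking]]:
    """Screen pathway pairs on kappa rankings with ForwardStop control.

    Same both-orientation evaluation and permutation machinery as the
    direct screen; the sorted p-values of all tested orientations within
    this direction feed the ForwardStop rule, and the rejected prefix
    becomes the call set. The reported ``q_value`` is the ForwardStop
    running mean (1/k) sum -log(1 - p_i) at the pair's rank. No CES cutoff
    is applied. Returns the calls and the per-pathway kappa rankings
    (mediator provenance included) for the mediator analysis.
    """
    cache = DeltaRhoCache(expr)
    rankings: dict[str, KappaRanking] = {}
    for name, genes in pathways.items():
        rankings[name] = compute_kappa(net, expr, genes, name=name, cache=cache)

    tested: list[tuple[str, str, float, float, int]] = []
    for a, b in enumerate_pairs(pathways):
        for p_name, q_name in ((a, b), (b, a)):
            sublist = rankings[p_name].sublist(direction)
            if not sublist:
                continue
            q_genes = pathways[q_name]
            genes_in = [g for g, _ in sublist if g in q_genes]
            if len(genes_in) < min_Q_overlap:
                continue
            rng = np.random.default_rng(
                pair_seed(seed, p_name, q_name, f"indirect-{direction}")
            )
            ces_obs, p = permutation_pvalue(sublist, q_genes, n_perm=n_perm, seed=rng)
            tested.append((p_name, q_name, ces_obs, p, len(genes_in)))

    if not tested:
        return [], rankings
    order = sorted(range(len(tested)), key=lambda i: (tested[i][3], tested[i][0], tested[i][1]))
    sorted_p = [tested[i][3] for i in order]
    k_hat = forward_stop(sorted_p, alpha)
    clamped = np.minimum(np.asarray(sorted_p), 1 - 1e-15)
    means = np.cumsum(-np.log1p(-clamped)) / np.arange(1, len(sorted_p) + 1)
    calls = []
    for rank, i in enumerate(order):
        p_name, q_name, ces_obs, p, n_hits = tested[i]
        rejected = rank < k_hat
        if rejected or return_all:
            calls.append(
                CePathwayCall(
                    pathway_P=p_name,
                    pathway_Q=q_name,
                    direction=direction,
                    ces=ces_obs,
                    p_perm=p,
                    q_value=float(means[rank]),
                    n_Q_in_ranking=n_hits,
                )
            )
    return calls, rankings
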