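"""Construction of the ceRNA relationship change network.

The network is an undirected graph over genes. An edge joins two genes
whose miRNA binding-site (family) overlap is larger than expected under a
hypergeometric draw from the active-family universe, after Benjamini-
Hochberg correction across all tested pairs. Each edge carries the Pearson
co-expression in the reference group (rho_normal), in the contrast group
(rho_tumor) and their difference delta_rho = rho_tumor - rho_normal: a
negative delta_rho marks a ceRNA relationship lost in the contrast
condition, a positive one a relationship gained.

Filters applied before testing, in order:
1. expressed genes: abundance >= min_abundance in strictly more than
   min_fraction of all samples (both groups pooled);
2. active miRNA families: mean abundance strictly between (lo, hi) across
   all samples — moderately expressed miRNAs are the ones with enough,
   but not saturating, repressive capacity to sustain competition;
3. genes with fewer than min_sites families within the active universe
   are removed before pair testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionDataset, MirnaTargetMap

__all__ = [
    "ChangeNetwork",
    "FilterReport",
    "OverlapResult",
    "filter_expressed_genes",
    "filter_active_mirnas",
    "test_binding_overlap",
    "build_change_network",
    "build_network",
    "write_edge_list",
    "read_edge_list",
]

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "gene_x",
    "gene_y",
    "rho_normal",
    "rho_tumor",
    "delta_rho",
    "overlap_k",
    "overlap_p",
    "overlap_q",
]


@dataclass(frozen=True)
class OverlapResult:
    """One tested gene pair: shared-family count and its significance."""

    gene_x: str
    gene_y: str
    k: int
    p: float
    q: float


@dataclass
class FilterReport:
    """Counts surviving each stage of the network-construction funnel."""

    n_genes_in: int = 0
    n_genes_expressed: int = 0
    n_genes_with_min_sites: int = 0
    n_mirna_families_active: int = 0
    n_pairs_tested: int = 0
    n_edges: int = 0
    n_edges_dropped_zero_variance: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


class ChangeNetwork:
    """Undirected gene graph annotated with co-expression changes.

    Thin wrapper over :class:`networkx.Graph`; edge attributes are
    ``rho_normal``, ``rho_tumor``, ``delta_rho``, ``overlap_k``,
    ``overlap_p``, ``overlap_q``.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_edge(self, x: str, y: str, **attrs) -> None:
        if x == y:
            raise ValueError("self-loops are not allowed")
        dr = attrs["rho_tumor"] - attrs["rho_normal"]
        if abs(attrs.get("delta_rho", dr) - dr) > 1e-12:
            raise ValueError("delta_rho must equal rho_tumor - rho_normal")
        attrs["delta_rho"] = dr
        self.graph.add_edge(x, y, **attrs)

    def has_edge(self, x: str, y: str) -> bool:
        return self.graph.has_edge(x, y)

    def delta_rho(self, x: str, y: str) -> float:
        return self.graph.edges[x, y]["delta_rho"]

    def neighbors(self, gene: str) -> Iterable[str]:
        if gene not in self.graph:
            return ()
        return self.graph.neighbors(gene)

    def edges(self, data: bool = True):
        return self.graph.edges(data=data)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


def filter_expressed_genes(
    expr: ExpressionDataset, min_abundance: float = 1.0, min_fraction: float = 0.8
) -> set[str]:
    """Genes with abundance >= min_abundance in strictly more than
    ``min_fraction`` of all samples (groups pooled)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    frac = (expr.values >= min_abundance).mean(axis=1)
    keep = {g for g, f in zip(expr.gene_ids, frac) if f > min_fraction}
    if not keep:
        logger.warning("expression filter retained zero genes")
    return keep


def filter_active_mirnas(
    mirna_expr: ExpressionDataset, lo: float = 0.01, hi: float = 100.0
) -> set[str]:
    """Families whose mean abundance across all samples lies strictly in (lo, hi)."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    means = mirna_expr.values.mean(axis=1)
    return {f for f, m in zip(mirna_expr.gene_ids, means) if lo < m < hi}


def test_binding_overlap(
    targets: MirnaTargetMap,
    genes: Iterable[str],
    min_sites: int = 6,
    q_cutoff: float = 0.05,
) -> list[OverlapResult]:
    """Hypergeometric test of shared miRNA families for every gene pair.

    For genes x, y with family sets F(x), F(y) inside a universe of size M,
    the p-value is the upper tail P(K >= |F(x) ∩ F(y)|) of a hypergeometric
    draw of |F(y)| balls from an urn with |F(x)| marked ones. B-H correction
    runs across all tested pairs; pairs with q < ``q_cutoff`` are returned.

    Genes with fewer than ``min_sites`` families (within the universe) are
    removed before any pair is formed.
    """
    universe_size = len(targets.universe)
    kept = sorted(
        g
        for g in genes
        if len(targets.families_of.get(g, frozenset())) >= min_sites
    )
    for g in kept:
        if len(targets.families_of[g]) > universe_size:
            raise ValueError(f"gene {g!r} has more families than the universe")
    n = len(kept)
    if n < 2:
        return []

    sets = [targets.families_of[g] for g in kept]
    sizes = np.array([len(s) for s in sets])
    pairs_i: list[int] = []
    pairs_j: list[int] = []
    ks: list[int] = []
    for i in range(n):
        fi = sets[i]
        for j in range(i + 1, n):
            pairs_i.append(i)
            pairs_j.append(j)
            ks.append(len(fi & sets[j]))
    ks_arr = np.array(ks)
    # sf(k-1) is the upper tail P(K >= k)
    pvals = stats.hypergeom.sf(
        ks_arr - 1, universe_size, sizes[np.array(pairs_i)], sizes[np.array(pairs_j)]
    )
    pvals = np.clip(pvals, 0.0, 1.0)
    qvals = stats.false_discovery_control(pvals, method="bh")
    results = [
        OverlapResult(kept[i], kept[j], int(k), float(p), float(q))
        for i, j, k, p, q in zip(pairs_i, pairs_j, ks_arr, pvals, qvals)
        if q < q_cutoff
    ]
    return results


def _group_correlations(
    expr: ExpressionDataset, genes: Sequence[str], group: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix within one group, plus a zero-variance mask."""
    idx = [expr.gene_index(g) for g in genes]
    cols = expr.sample_indices(group)
    if len(cols) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 samples")
    sub = expr.values[np.ix_(idx, cols)]
    sd = sub.std(axis=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    if corr.ndim == 0:  # single gene
        corr = np.array([[1.0]])
    return corr, zero_var


def build_change_network(
    expr: ExpressionDataset,
    significant_pairs: Sequence[OverlapResult],
    method: Literal["pearson", "spearman"] = "pearson",
    report: FilterReport | None = None,
) -> ChangeNetwork:
    """Annotate significant overlap pairs with per-group co-expression.

    rho_normal is computed within the reference group, rho_tumor within the
    contrast group (``expr.groups`` order). Edges touching a gene with zero
    variance in either group are dropped and counted in the report:
    an undefined correlation must not masquerade as absent co-expression.
    """
    net = ChangeNetwork()
    if not significant_pairs:
        return net
    genes = sorted({g for r in significant_pairs for g in (r.gene_x, r.gene_y)})
    missing = [g for g in genes if g not in expr._gene_index]
    if missing:
        raise ValueError(f"pairs reference genes absent from expression: {missing[:5]}")
    if method == "spearman":
        ranked = ExpressionDataset(
            gene_ids=expr.gene_ids,
            sample_ids=expr.sample_ids,
            values=_rank_within_groups(expr),
            condition_of=dict(expr.condition_of),
            groups=expr.groups,
        )
        expr_used = ranked
    else:
        expr_used = expr
    group_a, group_b = expr.groups
    corr_a, zv_a = _group_correlations(expr_used, genes, group_a)
    corr_b, zv_b = _group_correlations(expr_used, genes, group_b)
    pos = {g: i for i, g in enumerate(genes)}
    dropped = 0
    for r in significant_pairs:
        i, j = pos[r.gene_x], pos[r.gene_y]
        if zv_a[i] or zv_a[j] or zv_b[i] or zv_b[j]:
            dropped += 1
            continue
        net.add_edge(
            r.gene_x,
            r.gene_y,
            rho_normal=float(corr_a[i, j]),
            rho_tumor=float(corr_b[i, j]),
            overlap_k=r.k,
            overlap_p=r.p,
            overlap_q=r.q,
        )
    if dropped:
        logger.info("dropped %d edges touching zero-variance genes", dropped)
    if report is not None:
        report.n_edges = net.n_edges
        report.n_edges_dropped_zero_variance = dropped
    return net


def _rank_within_groups(expr: ExpressionDataset) -> np.ndarray:
    out = np.empty_like(expr.values)
    for group in expr.groups:
        cols = expr.sample_indices(group)
        out[:, cols] = stats.rankdata(expr.values[:, cols], axis=1)
    return out


def build_network(
    expr: ExpressionDataset,
    mirna_expr: ExpressionDataset,
    targets: MirnaTargetMap,
    min_abundance: float = 1.0,
    min_fraction: float = 0.8,
    mirna_lo: float = 0.01,
    mirna_hi: float = 100.0,
    min_sites: int = 6,
    overlap_q: float = 0.05,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[ChangeNetwork, FilterReport]:
    """Full funnel: expression filter → active families → overlap test → edges."""
    report = FilterReport(n_genes_in=expr.n_genes)
    expressed = filter_expressed_genes(expr, min_abundance, min_fraction)
    report.n_genes_expressed = len(expressed)
    active = filter_active_mirnas(mirna_expr, mirna_lo, mirna_hi)
    report.n_mirna_families_active = len(active)
    restricted = targets.restrict_universe(active)
    candidates = [g for g in expressed if g in restricted.families_of]
    report.n_genes_with_min_sites = sum(
        1 for g in candidates if len(restricted.families_of[g]) >= min_sites
    )
    results = test_binding_overlap(restricted, candidates, min_sites, overlap_q)
    report.n_pairs_tested = (
        report.n_genes_with_min_sites * (report.n_genes_with_min_sites - 1) // 2
    )
    net = build_change_network(expr, results, method=method, report=report)
    return net, report


def write_edge_list(net: ChangeNetwork, path: str | Path) -> None:
    rows = []
    for x, y, attrs in net.edges(data=True):
        a, b = sorted((x, y))
        rows.append(
            {
                "gene_x": a,
                "gene_y": b,
                "rho_normal": attrs["rho_normal"],
                "rho_tumor": attrs["rho_tumor"],
                "delta_rho": attrs["delta_rho"],
                "overlap_k": attrs["overlap_k"],
                "overlap_p": attrs["overlap_p"],
                "overlap_q": attrs["overlap_q"],
            }
        )
    frame = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if not frame.empty:
        frame = frame.sort_values(["gene_x", "gene_y"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edge_list(path: str | Path) -> ChangeNetwork:
    frame = pd.read_csv(path, sep="\t")
    net = ChangeNetwork()
    for row in frame.itertuples(index=False):
        net.add_edge(
            row.gene_x,
            row.gene_y,
            rho_normal=float(row.rho_normal),
            rho_tumor=float(row.rho_tumor),
            overlap_k=int(row.overlap_k),
            overlap_p=float(row.overlap_p),
            overlap_q=float(row.overlap_q),
        )
    return net
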