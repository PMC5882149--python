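"""Self-contained synthetic fixtures with planted ceRNA structure.

The generator emulates the statistical structure the pipeline consumes
rather than the underlying titration mechanics: co-expression is induced
by shared latent Gaussian drivers on the log scale, and binding-site
sharing by common core miRNA-family sets. Three layers are planted:

* co-targeting blocks (optional, off by default) — groups of genes sharing
  a core family set but no expression structure. Non-planted genes
  otherwise carry purely random target sets, so a null dataset yields an
  (almost always) empty change network; blocks can be switched on to
  stress the screens against a dense null network whose delta_rho is
  centered at 0;
* direct pairs — two pathways whose genes share families and a latent
  factor in one condition only, producing edges with delta_rho of the
  requested sign between the pathways;
* chains — two pathways connected only through dedicated mediator genes:
  pathway-mediator and mediator-pathway family sharing creates the two-hop
  edges, and one latent factor drives all three tiers in one condition,
  yielding sign-consistent co-expression changes along every chain while
  the endpoint pair shares no families (hence no direct edge).

miRNA family abundances are generated inside the moderate-expression
window for active families and far outside it for decoys, so the
active-family filter is exercised on every dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionDataset,
    MirnaTargetMap,
    PathwayCollection,
    write_gmt,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset", "generate_null_dataset", "write_fixture_dir"]

Direction = Literal["loss", "gain"]


@dataclass(frozen=True)
class PlantedPair:
    P_idx: int
    Q_idx: int
    direction: Direction
    effect: float


@dataclass(frozen=True)
class PlantedChain:
    P_idx: int
    mediator_count: int
    Q_idx: int
    direction: Direction
    effect: float


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale two-condition cohort: 200 genes in 20
    pathways of 8, 50 matched samples per group, 150 active miRNA families
    plus 20 decoys outside the moderate-expression window. ``effect`` is
    the log-scale co-expression induced in the structured condition, so a
    planted loss with effect 0.8 yields delta_rho near -0.8 on the log
    scale (slightly attenuated on the abundance scale).
    """

    seed: int
    n_genes: int = 200
    n_mirna_families: int = 300
    n_decoy_families: int = 20
    n_samples_per_group: int = 50
    n_pathways: int = 20
    pathway_size: int = 8
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_chains: list[PlantedChain] = field(default_factory=list)
    noise_sd: float = 0.5
    n_target_blocks: int = 0
    block_size: int = 12
    core_families: int = 10
    families_per_gene: int = 10
    n_silent_genes: int = 5
    pair_null_partners: int = 30
    chain_null_partners: int = 30

    def __post_init__(self) -> None:
        self.planted_pairs = [
            p if isinstance(p, PlantedPair) else PlantedPair(*p) for p in self.planted_pairs
        ]
        self.planted_chains = [
            c if isinstance(c, PlantedChain) else PlantedChain(*c)
            for c in self.planted_chains
        ]
        if self.n_pathways * self.pathway_size > self.n_genes:
            raise ValueError("pathway_size * n_pathways exceeds n_genes")
        used_pathways: set[int] = set()
        for p in self.planted_pairs:
            if not 0 < p.effect <= 1:
                raise ValueError("effect sizes must lie in (0, 1]")
            if p.direction not in ("loss", "gain"):
                raise ValueError(f"unknown direction {p.direction!r}")
            for idx in (p.P_idx, p.Q_idx):
                if not 0 <= idx < self.n_pathways:
                    raise ValueError(f"pathway index {idx} out of range")
                if idx in used_pathways:
                    raise ValueError("planted structures must use distinct pathways")
                used_pathways.add(idx)
        for c in self.planted_chains:
            if not 0 < c.effect <= 1:
                raise ValueError("effect sizes must lie in (0, 1]")
            if c.direction not in ("loss", "gain"):
                raise ValueError(f"unknown direction {c.direction!r}")
            if c.mediator_count < 1:
                raise ValueError("chains need at least one mediator")
            for idx in (c.P_idx, c.Q_idx):
                if not 0 <= idx < self.n_pathways:
                    raise ValueError(f"pathway index {idx} out of range")
                if idx in used_pathways:
                    raise ValueError("planted structures must use distinct pathways")
                used_pathways.add(idx)
        reserved = len(self.planted_pairs) + 2 * len(self.planted_chains)
        if reserved * self.core_families > self.n_mirna_families // 2:
            raise ValueError("not enough miRNA families for the planted core sets")


@dataclass
class GroundTruth:
    """What was planted, by name, for downstream recovery checks."""

    pathway_genes: dict[str, list[str]]
    planted_pairs: list[dict]
    planted_chains: list[dict]
    blocks: list[list[str]]
    silent_genes: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _sample_names(n_per_group: int) -> tuple[list[str], dict[str, str], dict[str, str]]:
    normals = [f"N{i:03d}" for i in range(n_per_group)]
    tumors = [f"T{i:03d}" for i in range(n_per_group)]
    condition = {**{s: "normal" for s in normals}, **{s: "tumor" for s in tumors}}
    pairing = dict(zip(normals, tumors))
    return normals + tumors, condition, pairing


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, ExpressionDataset, MirnaTargetMap, PathwayCollection, GroundTruth]:
    """Generate (mRNA, miRNA, target map, pathways, ground truth) for one study."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    n_path_genes = spec.n_pathways * spec.pathway_size

    # silent genes sit outside pathways and fail the expression filter
    silent = genes[-spec.n_silent_genes:] if spec.n_silent_genes else []
    assignable = genes[: spec.n_genes - spec.n_silent_genes]
    if n_path_genes > len(assignable):
        raise ValueError("not enough non-silent genes for the pathways")
    perm = list(rng.permutation(assignable))
    pathway_names = [f"PATH{i:02d}" for i in range(spec.n_pathways)]
    pathway_genes = {
        name: sorted(perm[i * spec.pathway_size : (i + 1) * spec.pathway_size])
        for i, name in enumerate(pathway_names)
    }
    free_genes = perm[n_path_genes:]  # mediator pool

    families = [f"F{i:03d}" for i in range(spec.n_mirna_families)]
    decoys = [f"D{i:02d}" for i in range(spec.n_decoy_families)]

    # reserve disjoint core family sets for the planted structures
    fam_perm = list(rng.permutation(families))
    cursor = 0

    def take_core() -> list[str]:
        nonlocal cursor
        core = fam_perm[cursor : cursor + spec.core_families]
        cursor += spec.core_families
        return core

    pair_cores = [take_core() for _ in spec.planted_pairs]
    chain_cores = [(take_core(), take_core()) for _ in spec.planted_chains]
    block_pool = fam_perm[cursor:]

    families_of: dict[str, set[str]] = {}
    for g in genes:
        base = rng.choice(len(families), size=spec.families_per_gene, replace=False)
        fams = {families[i] for i in base}
        # a couple of decoy families per gene exercise the activity filter
        fams.update(rng.choice(decoys, size=min(2, len(decoys)), replace=False))
        families_of[g] = fams

    # mediators must be non-pathway genes; take them from the free pool first
    chain_mediator_sets: list[list[str]] = []
    for planted in spec.planted_chains:
        if len(free_genes) < planted.mediator_count:
            raise ValueError("not enough non-pathway genes for chain mediators")
        chain_mediator_sets.append(sorted(free_genes[: planted.mediator_count]))
        free_genes = free_genes[planted.mediator_count :]

    # null partners share the planted core families (so they enter the
    # rankings as misses with small co-expression changes) but carry no
    # expression structure; without them a planted ranking would consist of
    # planted genes only and the label-permutation test would be degenerate.
    # They come from the free pool first, then from non-planted pathways
    # (other pathways' genes sharing binding sites is the realistic case).
    planted_path_idx = {p.P_idx for p in spec.planted_pairs} | {
        p.Q_idx for p in spec.planted_pairs
    } | {c.P_idx for c in spec.planted_chains} | {c.Q_idx for c in spec.planted_chains}
    unplanted_path_genes = [
        g
        for i, name in enumerate(pathway_names)
        if i not in planted_path_idx
        for g in pathway_genes[name]
    ]
    partner_pool = list(free_genes) + list(rng.permutation(unplanted_path_genes))

    def take_partners(count: int) -> list[str]:
        nonlocal partner_pool
        if len(partner_pool) < count:
            raise ValueError("not enough genes for null partners")
        taken, partner_pool = partner_pool[:count], partner_pool[count:]
        return sorted(taken)

    pair_partner_sets = [take_partners(spec.pair_null_partners) for _ in spec.planted_pairs]
    chain_partner_sets = [
        take_partners(spec.chain_null_partners) for _ in spec.planted_chains
    ]
    planted_genes: set[str] = set(
        g
        for ms in chain_mediator_sets + chain_partner_sets + pair_partner_sets
        for g in ms
    )
    for planted in spec.planted_pairs:
        for idx in (planted.P_idx, planted.Q_idx):
            planted_genes.update(pathway_genes[pathway_names[idx]])
    for planted in spec.planted_chains:
        for idx in (planted.P_idx, planted.Q_idx):
            planted_genes.update(pathway_genes[pathway_names[idx]])

    block_gene_pool = [g for g in assignable if g not in planted_genes]
    if len(block_gene_pool) < spec.block_size:
        raise ValueError("not enough unplanted genes for co-targeting blocks")
    blocks: list[list[str]] = []
    for _ in range(spec.n_target_blocks):
        members = sorted(rng.choice(block_gene_pool, size=spec.block_size, replace=False))
        core = rng.choice(len(block_pool), size=spec.core_families, replace=False)
        core_set = {block_pool[i] for i in core}
        for g in members:
            families_of[g].update(core_set)
        blocks.append(members)

    gt_pairs: list[dict] = []
    for planted, core, partners in zip(spec.planted_pairs, pair_cores, pair_partner_sets):
        p_name, q_name = pathway_names[planted.P_idx], pathway_names[planted.Q_idx]
        for g in pathway_genes[p_name] + pathway_genes[q_name] + partners:
            families_of[g].update(core)
        gt_pairs.append(
            {
                "pathway_P": p_name,
                "pathway_Q": q_name,
                "direction": planted.direction,
                "effect": planted.effect,
            }
        )

    gt_chains: list[dict] = []
    chain_members: list[tuple[PlantedChain, list[str], list[str], list[str]]] = []
    for planted, (core_a, core_b), mediators, partners in zip(
        spec.planted_chains, chain_cores, chain_mediator_sets, chain_partner_sets
    ):
        p_name, q_name = pathway_names[planted.P_idx], pathway_names[planted.Q_idx]
        for g in pathway_genes[p_name] + mediators:
            families_of[g].update(core_a)
        for g in mediators + pathway_genes[q_name] + partners:
            families_of[g].update(core_b)
        chain_members.append(
            (planted, pathway_genes[p_name], mediators, pathway_genes[q_name])
        )
        gt_chains.append(
            {
                "pathway_P": p_name,
                "pathway_Q": q_name,
                "direction": planted.direction,
                "effect": planted.effect,
                "mediators": mediators,
            }
        )

    sample_ids, condition_of, pairing = _sample_names(spec.n_samples_per_group)
    n_samples = len(sample_ids)
    normal_cols = np.arange(spec.n_samples_per_group)
    tumor_cols = np.arange(spec.n_samples_per_group, n_samples)

    gene_pos = {g: i for i, g in enumerate(genes)}
    log_signal = rng.standard_normal((spec.n_genes, n_samples))

    def plant_factor(members: list[str], direction: Direction, effect: float) -> None:
        cols = normal_cols if direction == "loss" else tumor_cols
        factor = rng.standard_normal(len(cols))
        rows = [gene_pos[g] for g in members]
        noise = rng.standard_normal((len(rows), len(cols)))
        log_signal[np.ix_(rows, cols)] = (
            np.sqrt(effect) * factor[None, :] + np.sqrt(1.0 - effect) * noise
        )

    for planted, core in zip(spec.planted_pairs, pair_cores):
        p_name, q_name = pathway_names[planted.P_idx], pathway_names[planted.Q_idx]
        plant_factor(
            pathway_genes[p_name] + pathway_genes[q_name], planted.direction, planted.effect
        )
    for planted, p_genes, mediators, q_genes in chain_members:
        plant_factor(p_genes + mediators + q_genes, planted.direction, planted.effect)

    mu = rng.normal(3.0, 0.7, size=spec.n_genes)
    for g in silent:
        mu[gene_pos[g]] = -5.0
    values = np.exp(mu[:, None] + spec.noise_sd * log_signal)

    expr = ExpressionDataset(
        gene_ids=genes,
        sample_ids=sample_ids,
        values=values,
        condition_of=condition_of,
        groups=("normal", "tumor"),
        pairing=pairing,
    )

    # miRNA families: active ones inside the moderate window, decoys outside
    fam_ids = families + decoys
    fam_mu = np.concatenate(
        [
            rng.uniform(np.log(0.1), np.log(30.0), size=len(families)),
            np.where(
                rng.random(len(decoys)) < 0.5,
                np.log(1e-4),
                np.log(5e3),
            ),
        ]
    )
    mirna_values = np.exp(
        fam_mu[:, None] + 0.2 * rng.standard_normal((len(fam_ids), n_samples))
    )
    mirna = ExpressionDataset(
        gene_ids=fam_ids,
        sample_ids=sample_ids,
        values=mirna_values,
        condition_of=condition_of,
        groups=("normal", "tumor"),
    )

    targets = MirnaTargetMap(
        families_of={g: frozenset(f) for g, f in families_of.items()},
        universe=frozenset(fam_ids),
    )
    pathways = PathwayCollection(
        pathways={n: frozenset(g) for n, g in pathway_genes.items()},
        source="synthetic",
    )
    truth = GroundTruth(
        pathway_genes={n: list(g) for n, g in pathway_genes.items()},
        planted_pairs=gt_pairs,
        planted_chains=gt_chains,
        blocks=blocks,
        silent_genes=list(silent),
    )
    return expr, mirna, targets, pathways, truth


def generate_null_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, ExpressionDataset, MirnaTargetMap, PathwayCollection, GroundTruth]:
    """As :func:`generate_dataset` with all planted structure removed."""
    return generate_dataset(replace(spec, planted_pairs=[], planted_chains=[]))


def write_fixture_dir(
    spec: SyntheticSpec, out_dir: str | Path, null: bool = False
) -> Path:
    """Write a full fixture directory (TSV/GMT/JSON) for CLI consumption."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = generate_null_dataset if null else generate_dataset
    expr, mirna, targets, pathways, truth = gen(spec)

    def write_expr(ds: ExpressionDataset, name: str) -> None:
        frame = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids)
        frame.index.name = "gene_id"
        frame.to_csv(out / name, sep="\t", float_format="%.6g")

    write_expr(expr, "expression.tsv")
    write_expr(mirna, "mirna_expression.tsv")

    rows = []
    for s in expr.sample_ids:
        row = {"sample_id": s, "group": expr.condition_of[s]}
        rows.append(row)
    if expr.pairing:
        pair_of = {}
        for i, (a, b) in enumerate(sorted(expr.pairing.items())):
            pair_of[a] = pair_of[b] = f"PAIR{i:03d}"
        for row in rows:
            row["pair_id"] = pair_of.get(row["sample_id"], "")
    pd.DataFrame(rows).to_csv(out / "conditions.tsv", sep="\t", index=False)

    target_rows = [
        {"gene_id": g, "mirna_family_id": f, "score": 1.0}
        for g in sorted(targets.families_of)
        for f in sorted(targets.families_of[g])
    ]
    pd.DataFrame(target_rows).to_csv(out / "targets.tsv", sep="\t", index=False)
    write_gmt(pathways, out / "pathways.gmt")
    (out / "ground_truth.json").write_text(truth.to_json())
    return out
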