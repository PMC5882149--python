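"""Shared fixtures: small deterministic datasets and random-network builders."""

from __future__ import annotations

import numpy as np
import pytest

from macpath.cerna_network import ChangeNetwork
from macpath.io_formats import ExpressionDataset
from macpath.synthetic_data import (
    PlantedChain,
    PlantedPair,
    SyntheticSpec,
    generate_dataset,
)


def make_expression(
    values: np.ndarray,
    gene_ids: list[str] | None = None,
    n_normal: int | None = None,
) -> ExpressionDataset:
    """Wrap a raw matrix into a two-group dataset (first half normal)."""
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if n_normal is None:
        n_normal = n_samples // 2
    sample_ids = [f"s{i}" for i in range(n_samples)]
    condition_of = {
        s: ("normal" if i < n_normal else "tumor") for i, s in enumerate(sample_ids)
    }
    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        condition_of=condition_of,
        groups=("normal", "tumor"),
    )


def random_network(
    rng: np.random.Generator, n_genes: int, edge_prob: float = 0.2
) -> ChangeNetwork:
    """A random change network with arbitrary per-group correlations."""
    net = ChangeNetwork()
    genes = [f"g{i}" for i in range(n_genes)]
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_prob:
                rho_n = float(rng.uniform(-1, 1))
                rho_t = float(rng.uniform(-1, 1))
                net.add_edge(genes[i], genes[j], rho_normal=rho_n, rho_tumor=rho_t,
                             overlap_k=5, overlap_p=1e-4, overlap_q=1e-3)
    return net


@pytest.fixture(scope="session")
def planted_study():
    """One synthetic study with a planted direct loss and an indirect loss chain."""
    spec = SyntheticSpec(
        seed=20240917,
        planted_pairs=[PlantedPair(0, 1, "loss", 0.8)],
        planted_chains=[PlantedChain(2, 6, 3, "loss", 0.8)],
    )
    return spec, generate_dataset(spec)
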