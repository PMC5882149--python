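"""Readers and writers for the external formats the pipeline touches.

All downstream modules operate on the in-memory domain types defined here:
:class:`ExpressionDataset` (genes × samples abundance with a two-group
condition map), :class:`MirnaTargetMap` (gene → miRNA-family sets) and
:class:`PathwayCollection` (ordered GMT-style gene sets).

Gene identifiers are opaque strings throughout; no symbol/accession mapping
is performed. Missing values in any table are an error, never imputed —
the correlation machinery downstream assumes complete vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "MirnaTargetMap",
    "PathwayCollection",
    "read_expression_table",
    "read_gmt",
    "read_mirna_target_table",
    "write_results_table",
    "RESULT_COLUMNS",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format or invariants."""


@dataclass
class ExpressionDataset:
    """A genes × samples abundance matrix with a two-group condition map.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique, ordered gene identifiers (rows of ``values``).
    sample_ids : sequence of str
        Unique, ordered sample identifiers (columns of ``values``).
    values : ndarray of shape (n_genes, n_samples)
        Non-negative abundances (FPKM-like units). NaN is rejected.
    condition_of : mapping sample_id -> group label
        Exactly two distinct groups, both non-empty. The first group in
        ``groups`` plays the reference role (e.g. normal), the second the
        contrast role (e.g. tumor).
    groups : (str, str), optional
        Explicit (reference, contrast) ordering. Defaults to order of first
        appearance in ``condition_of``.
    pairing : mapping, optional
        Bijection reference-sample -> contrast-sample for matched designs.
        Carried as metadata only; no paired statistic is computed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition_of: dict[str, str]
    groups: tuple[str, str] | None = None
    pairing: dict[str, str] | None = None
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise FormatError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise FormatError("expression matrix contains missing values")
        if (self.values < 0).any():
            raise FormatError("expression matrix contains negative abundances")
        unknown = set(self.condition_of) - set(self.sample_ids)
        if unknown:
            raise FormatError(f"condition map lists unknown sample(s): {sorted(unknown)}")
        missing = set(self.sample_ids) - set(self.condition_of)
        if missing:
            raise FormatError(f"sample(s) without condition label: {sorted(missing)}")
        labels = list(dict.fromkeys(self.condition_of[s] for s in self.sample_ids))
        if len(labels) != 2:
            raise FormatError(f"expected exactly 2 condition groups, found {labels}")
        if self.groups is None:
            self.groups = (labels[0], labels[1])
        elif set(self.groups) != set(labels):
            raise FormatError(f"declared groups {self.groups} do not match labels {labels}")
        if self.pairing is not None:
            self._validate_pairing()
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def _validate_pairing(self) -> None:
        a, b = self.groups
        a_samples = set(self.samples_in(a))
        b_samples = set(self.samples_in(b))
        if set(self.pairing) != a_samples or set(self.pairing.values()) != b_samples:
            raise FormatError("pairing map is not a bijection between the two groups")
        if len(set(self.pairing.values())) != len(self.pairing):
            raise FormatError("pairing map is not injective")

    @property
    def paired(self) -> bool:
        return self.pairing is not None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of[s] == group]

    def sample_indices(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.condition_of[s] == group],
            dtype=int,
        )

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        """Return a dataset restricted to ``genes`` (order preserved from self)."""
        keep = [g for g in self.gene_ids if g in set(genes)]
        idx = [self._gene_index[g] for g in keep]
        return ExpressionDataset(
            gene_ids=keep,
            sample_ids=self.sample_ids,
            values=self.values[idx],
            condition_of=dict(self.condition_of),
            groups=self.groups,
            pairing=dict(self.pairing) if self.pairing else None,
        )


@dataclass
class MirnaTargetMap:
    """Gene → set of miRNA-family ids, with the family universe.

    Families, not mature miRNAs, are the unit of binding-site sharing: the
    hypergeometric overlap test downstream draws families from ``universe``.
    """

    families_of: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.families_of = {g: frozenset(f) for g, f in self.families_of.items()}
        self.universe = frozenset(self.universe)
        for gene, fams in self.families_of.items():
            extra = fams - self.universe
            if extra:
                raise FormatError(
                    f"gene {gene!r} carries families outside the universe: {sorted(extra)}"
                )

    def restrict_universe(self, active: Iterable[str]) -> "MirnaTargetMap":
        """Intersect every gene's family set (and the universe) with ``active``."""
        active = frozenset(active) & self.universe
        return MirnaTargetMap(
            families_of={g: f & active for g, f in self.families_of.items()},
            universe=active,
        )

    def genes(self) -> list[str]:
        return list(self.families_of)


@dataclass
class PathwayCollection:
    """Ordered mapping pathway name → gene set, as read from a GMT file."""

    pathways: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        self.pathways = {n: frozenset(g) for n, g in self.pathways.items()}
        for name, genes in self.pathways.items():
            if not genes:
                raise FormatError(f"pathway {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def names(self) -> list[str]:
        return list(self.pathways)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.pathways[name]

    def items(self):
        return self.pathways.items()


def _first_duplicate(seq: Sequence[str]) -> str:
    seen: set[str] = set()
    for item in seq:
        if item in seen:
            return item
        seen.add(item)
    return ""


def read_expression_table(path: str | Path, condition_map_path: str | Path) -> ExpressionDataset:
    """Read a TSV expression matrix plus its sample-condition map.

    The matrix has a header row of sample ids and gene ids in the first
    column. The condition map is a TSV with columns ``sample_id``, ``group``
    and optionally ``pair_id``; samples sharing a pair_id across the two
    groups form a matched pair.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed expression table: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = frame.index[np.isnan(values).any(axis=1)][0]
        raise FormatError(f"{path}: missing value in row {bad!r}")

    cond = pd.read_csv(condition_map_path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(cond.columns):
        raise FormatError(f"{condition_map_path}: needs columns {sorted(required)}")
    condition_of = dict(zip(cond["sample_id"], cond["group"]))
    if len(condition_of) != len(cond):
        raise FormatError(f"{condition_map_path}: duplicate sample_id entries")

    pairing = None
    if "pair_id" in cond.columns and cond["pair_id"].notna().any():
        groups = list(dict.fromkeys(cond["group"]))
        by_pair: dict[str, dict[str, str]] = {}
        for _, row in cond.iterrows():
            if pd.isna(row.get("pair_id")):
                continue
            by_pair.setdefault(row["pair_id"], {})[row["group"]] = row["sample_id"]
        pairing = {}
        for pair_id, members in by_pair.items():
            if len(members) != 2:
                raise FormatError(f"{condition_map_path}: pair {pair_id!r} is incomplete")
            pairing[members[groups[0]]] = members[groups[1]]

    return ExpressionDataset(
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(c) for c in frame.columns],
        values=values,
        condition_of=condition_of,
        pairing=pairing,
    )


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT pathway collection (name, description, genes...; tab-separated)."""
    path = Path(path)
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} lists no genes")
            pathways[name] = genes
    return PathwayCollection(pathways=pathways, source=str(path))


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, genes in collection.items():
            handle.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_mirna_target_table(
    path: str | Path, min_score: float | None = 0.0
) -> MirnaTargetMap:
    """Read a gene → miRNA-family binding-site table.

    TSV columns: ``gene_id``, ``mirna_family_id`` and optionally ``score``
    (a Pct-like site-confidence value). Rows with score <= ``min_score``
    are dropped; pass ``min_score=None`` to keep all rows. The family
    universe is every family id seen in the file *before* filtering, so a
    stringent score cutoff shrinks gene sets but not the urn.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "mirna_family_id": str})
    if not {"gene_id", "mirna_family_id"}.issubset(table.columns):
        raise FormatError(f"{path}: needs columns gene_id, mirna_family_id")
    universe = frozenset(table["mirna_family_id"])
    if min_score is not None and "score" in table.columns:
        table = table[table["score"].astype(float) > min_score]
    if table.empty:
        raise FormatError(f"{path}: no target rows remain after score filtering")
    families_of = {
        gene: frozenset(sub["mirna_family_id"])
        for gene, sub in table.groupby("gene_id", sort=False)
    }
    return MirnaTargetMap(families_of=families_of, universe=universe)


RESULT_COLUMNS = [
    "pathway_P",
    "pathway_Q",
    "direction",
    "CES",
    "p_perm",
    "q_value",
    "n_contributing_genes",
]


def write_results_table(calls: Iterable, path: str | Path) -> None:
    """Write cePathway calls as a TSV, ordered by (q, CES desc, names)."""
    rows = [
        {
            "pathway_P": c.pathway_P,
            "pathway_Q": c.pathway_Q,
            "direction": c.direction,
            "CES": round(float(c.ces), 6),
            "p_perm": round(float(c.p_perm), 6),
            "q_value": round(float(c.q_value), 6),
            "n_contributing_genes": int(c.n_Q_in_ranking),
        }
        for c in calls
    ]
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not frame.empty:
        frame = frame.sort_values(
            by=["q_value", "CES", "pathway_P", "pathway_Q"],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Parse a results TSV back into a DataFrame (round-trip of the writer)."""
    return pd.read_csv(path, sep="\t")
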