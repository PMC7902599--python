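"""Phylostratigraphic age assignment from homology hit tables.

Each locus is assigned the oldest (root-most) phylogenetic node at which a
homolog is detectable: for every hit passing the E-value filter the lowest
common ancestor of the hit taxon's lineage and the focal-species lineage
is computed, and the stratum is the root-most of those LCA nodes.  A locus
with no passing hits is specific to the focal species.

Lineages come from a flat two-column file (taxon, semicolon-joined
root-to-tip lineage) which is treated as authoritative; lineages are
compared positionally from the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

HIT_COLUMNS = ["query", "subject_taxon", "pident", "evalue"]


@dataclass(frozen=True)
class Lineage:
    """Ordered node list, root first, terminating in the taxon itself."""

    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("lineage must be non-empty")

    @property
    def species(self) -> str:
        return self.nodes[-1]

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "Lineage":
        return cls(tuple(n.strip() for n in text.split(sep) if n.strip()))


@dataclass(frozen=True)
class PhylostratumAssignment:
    locus: str
    stratum: str
    n_hits: int


def read_lineage_file(path: str | Path) -> dict[str, Lineage]:
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "lineage"], dtype=str)
    return {row.taxon: Lineage.from_string(row.lineage) for row in df.itertuples()}


def read_hit_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=HIT_COLUMNS, dtype={"query": str, "subject_taxon": str}
    )


def lca_depth(hit_lineage: Lineage, focal_lineage: Lineage) -> tuple[int, str]:
    """Deepest-from-root shared node; returned as (depth index, node name)."""
    depth = -1
    node = None
    for i, (a, b) in enumerate(zip(hit_lineage.nodes, focal_lineage.nodes)):
        if a != b:
            break
        depth, node = i, a
    if node is None:
        raise ValueError(
            f"lineages share no root node: {hit_lineage.nodes[0]!r} vs "
            f"{focal_lineage.nodes[0]!r}"
        )
    return depth, node


def assign_phylostratum(
    locus: str,
    hits: pd.DataFrame,
    lineages: dict[str, Lineage],
    focal_lineage: Lineage,
    evalue_max: float = 1e-5,
) -> PhylostratumAssignment:
    """Stratum of one locus: root-most LCA over all passing non-self hits.

    ``hits`` rows need ``subject_taxon`` and ``evalue`` columns.  Hits to
    the focal species itself are ignored (the homology search this models
    excludes self-matches); with no passing hits the stratum is the focal
    species.
    """
    passing = hits[
        (pd.to_numeric(hits.evalue) <= evalue_max)
        & (hits.subject_taxon != focal_lineage.species)
    ]
    best_depth = len(focal_lineage.nodes) - 1
    stratum = focal_lineage.species
    n = 0
    for taxon in passing.subject_taxon:
        if taxon not in lineages:
            raise KeyError(f"taxon {taxon!r} missing from the lineage file")
        depth, node = lca_depth(lineages[taxon], focal_lineage)
        n += 1
        if depth < best_depth:
            best_depth, stratum = depth, node
    return PhylostratumAssignment(locus=locus, stratum=stratum, n_hits=n)


def assign_all(
    hit_table: pd.DataFrame,
    lineages: dict[str, Lineage],
    focal_lineage: Lineage,
    loci: list[str],
    evalue_max: float = 1e-5,
) -> pd.DataFrame:
    """Per-locus strata for a cohort; loci absent from the table get the focal stratum."""
    grouped = dict(tuple(hit_table.groupby("query", sort=False)))
    empty = hit_table.iloc[0:0]
    rows = []
    for locus in loci:
        a = assign_phylostratum(
            locus, grouped.get(locus, empty), lineages, focal_lineage, evalue_max
        )
        rows.append({"locus": a.locus, "stratum": a.stratum, "n_hits": a.n_hits})
    return pd.DataFrame(rows).set_index("locus")
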