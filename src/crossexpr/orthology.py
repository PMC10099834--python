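"""Ortholog recovery from pairwise similarity-hit tables.

One-to-one orthologs are recovered with anchored reciprocal best hits (RBH):
for each non-anchor species, genes that are mutually each other's unique
top-bitscore hit against the anchor species (below an e-value ceiling) form a
pair, and anchor genes with a partner in every species yield a tuple.
Orthogroups (gene families, possibly with several paralogs per species) are a
graph-clustering surrogate: connected components of the graph whose edges are
cross-species RBH pairs plus within-species bidirectional best hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .types import CrossExprError, ExpressionMatrix, concat_matrices

DEFAULT_EVALUE_MAX = 1e-10


@dataclass
class HitTable:
    """Pairwise similarity hits oriented query-species -> subject-species."""

    rows: pd.DataFrame  # columns include query, subject, bitscore, evalue
    query_species: str
    subject_species: str

    def __post_init__(self) -> None:
        need = {"query", "subject", "bitscore", "evalue"}
        missing = need - set(self.rows.columns)
        if missing:
            raise CrossExprError(f"hit table missing columns {sorted(missing)}")


@dataclass
class OrthologSet:
    anchor_species: str
    species: tuple[str, ...]
    tuples: list[dict[str, str]]  # each maps species -> gene id


@dataclass
class Orthogroup:
    family_id: str
    members: dict[str, list[str]]  # species -> gene ids


def _best_hits(table: pd.DataFrame, evalue_max: float) -> dict[str, str]:
    """Unique top-bitscore subject per query; tied top scores disqualify."""
    ok = table[table["evalue"] < evalue_max]
    best: dict[str, str] = {}
    for query, grp in ok.groupby("query", sort=False):
        top = grp["bitscore"].max()
        winners = grp.loc[grp["bitscore"] == top, "subject"].unique()
        if len(winners) == 1:
            best[str(query)] = str(winners[0])
    return best


def reciprocal_best_hits(
    ab: HitTable, ba: HitTable, evalue_max: float = DEFAULT_EVALUE_MAX
) -> list[tuple[str, str]]:
    """RBH pairs (a, b): b is a's unique best hit and vice versa.

    Best hits are ranked by bitscore; e-value acts only as a filter.  A query
    whose top bitscore is tied across several subjects yields no pair.
    """
    if ab.query_species != ba.subject_species or ab.subject_species != ba.query_species:
        raise CrossExprError(
            "hit tables are not reciprocally oriented: "
            f"{ab.query_species}->{ab.subject_species} vs "
            f"{ba.query_species}->{ba.subject_species}"
        )
    fwd = _best_hits(ab.rows, evalue_max)
    rev = _best_hits(ba.rows, evalue_max)
    pairs = [(a, b) for a, b in fwd.items() if rev.get(b) == a]
    pairs.sort()
    return pairs


def anchor_one_to_one(
    rbh_per_species: Mapping[str, Sequence[tuple[str, str]]], anchor: str
) -> OrthologSet:
    """One tuple per anchor gene with an RBH partner in every other species.

    ``rbh_per_species[sp]`` holds (anchor gene, sp gene) pairs.
    """
    if not rbh_per_species:
        raise CrossExprError("no RBH pair lists given")
    maps: dict[str, dict[str, str]] = {}
    for sp, pairs in rbh_per_species.items():
        if pairs is None:
            raise CrossExprError(f"missing RBH pairs for species {sp}")
        maps[sp] = {a: b for a, b in pairs}
    common = set.intersection(*(set(m) for m in maps.values())) if maps else set()
    tuples = []
    for a in sorted(common):
        tup = {anchor: a}
        for sp, m in maps.items():
            tup[sp] = m[a]
        tuples.append(tup)
    return OrthologSet(
        anchor_species=anchor, species=(anchor, *sorted(maps)), tuples=tuples
    )


def infer_orthogroups(
    tables: Iterable[HitTable], evalue_max: float = DEFAULT_EVALUE_MAX
) -> list[Orthogroup]:
    """Families as connected components of the best-hit graph.

    Edges: cross-species RBH pairs, plus within-species mutual or one-sided
    best hits (a gene and its top within-species match).  Every gene seen in
    any table appears in exactly one family; genes with no edges are
    singletons.  Families are ordered and named deterministically by their
    lexicographically smallest member.
    """
    tables = list(tables)
    by_pair: dict[tuple[str, str], HitTable] = {}
    genes: set[tuple[str, str]] = set()
    for t in tables:
        by_pair[(t.query_species, t.subject_species)] = t
        for g in t.rows["query"]:
            genes.add((t.query_species, str(g)))
        for g in t.rows["subject"]:
            genes.add((t.subject_species, str(g)))

    g = nx.Graph()
    g.add_nodes_from(genes)
    for (a, b), t in by_pair.items():
        if a == b:
            best = _best_hits(
                t.rows[t.rows["query"] != t.rows["subject"]], evalue_max
            )
            for q, s in best.items():
                g.add_edge((a, q), (a, s))
        elif (b, a) in by_pair and a < b:
            for q, s in reciprocal_best_hits(t, by_pair[(b, a)], evalue_max):
                g.add_edge((a, q), (b, s))

    comps = sorted(nx.connected_components(g), key=lambda c: min(n[1] for n in c))
    out = []
    for i, comp in enumerate(comps):
        members: dict[str, list[str]] = {}
        for sp, gid in sorted(comp):
            members.setdefault(sp, []).append(gid)
        out.append(Orthogroup(family_id=f"FAM{i:05d}", members=members))
    return out


def family_map(families: Iterable[Orthogroup]) -> dict[str, str]:
    """gene id -> family id over a set of orthogroups (genes must be unique)."""
    out: dict[str, str] = {}
    for fam in families:
        for genes in fam.members.values():
            for gid in genes:
                if gid in out:
                    raise CrossExprError(f"gene {gid} appears in two families")
                out[gid] = fam.family_id
    return out


def build_ortholog_matrix(
    ortho: OrthologSet, matrices: Mapping[str, ExpressionMatrix]
) -> ExpressionMatrix:
    """Cross-species expression matrix over one-to-one ortholog tuples.

    Rows are tuples named by the anchor gene; columns are the union of all
    species' samples; values are copied unchanged on the input scale.
    """
    if not ortho.tuples:
        raise CrossExprError("empty ortholog set")
    scale = next(iter(matrices.values())).scale
    blocks = []
    for sp in ortho.species:
        if sp not in matrices:
            raise CrossExprError(f"no expression matrix for species {sp}")
        m = matrices[sp]
        if m.scale != scale:
            raise CrossExprError("species matrices on different scales")
        wanted = [t[sp] for t in ortho.tuples]
        missing = set(wanted) - set(m.values.index)
        if missing:
            gid = sorted(missing)[0]
            raise CrossExprError(f"gene {gid} missing from species {sp} matrix")
        block = m.values.loc[wanted].copy()
        block.index = [t[ortho.anchor_species] for t in ortho.tuples]
        blocks.append(ExpressionMatrix(block, m.samples, scale))
    return concat_matrices(blocks, scale=scale)
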