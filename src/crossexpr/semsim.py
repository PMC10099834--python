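"""GO enrichment and graph-based semantic similarity with a permutation null.

Enrichment of a study gene set is a hypergeometric upper-tail test per term
(direct annotations propagated to ancestors through both is_a and part_of
edges) with Benjamini-Hochberg correction.  Term-term similarity is Wang's
graph measure: each ancestor a of a term t receives an S-value, the maximum
over paths from t to a of the product of edge weights (is_a 0.8, part_of
0.6, S_t(t) = 1), and

    sim(t1, t2) = sum_{a in common ancestors} (S_t1(a) + S_t2(a))
                  / (SV(t1) + SV(t2)),   SV(t) = sum_a S_t(a).

Term-set similarity is the best-match average (BMA).  Significance of an
observed set similarity is assessed against a null of uniformly drawn term
sets of the same sizes; a value above the null's 95th percentile is called
significant (one-sided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata import GoDag
from .types import CrossExprError, ExpressionMatrix

EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class SemSimResult:
    observed_ss: float
    null_values: np.ndarray
    p90: float
    p95: float
    significant: bool
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# top expressed genes and enrichment
# ---------------------------------------------------------------------------


def top_expressed_genes(m: ExpressionMatrix, tissue: str, k: int = 500) -> list[str]:
    """Top-k genes by mean expression over the tissue's samples.

    Ties at the cutoff are broken toward the lexicographically smaller gene
    id, making the selection deterministic.
    """
    samples = m.sample_ids_where(tissue=tissue)
    if not samples:
        raise CrossExprError(f"tissue {tissue} has no samples")
    means = m.values[samples].mean(axis=1)
    if k > len(means):
        import warnings

        warnings.warn(f"k={k} exceeds gene count {len(means)}; returning all genes")
        k = len(means)
    ranked = means.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:k])


def _ancestors(dag: GoDag, term: str) -> set[str]:
    # child -> parent edges: ancestors are networkx descendants
    import networkx as nx

    return set(nx.descendants(dag.graph, term)) | {term}


def propagate_annotations(
    ann: Mapping[str, Iterable[str]], dag: GoDag
) -> dict[str, set[str]]:
    """Close each gene's term set over ancestors (is_a and part_of)."""
    cache: dict[str, set[str]] = {}

    def anc(t: str) -> set[str]:
        if t not in cache:
            cache[t] = _ancestors(dag, t)
        return cache[t]

    out: dict[str, set[str]] = {}
    for gene, terms in ann.items():
        full: set[str] = set()
        for t in terms:
            if t not in dag.graph:
                raise CrossExprError(f"annotation term {t} not in ontology")
            full |= anc(t)
        out[gene] = full
    return out


def enrich_terms(
    study: Iterable[str],
    ann: Mapping[str, Iterable[str]],
    background: Iterable[str],
    dag: GoDag,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``study`` within ``background``.

    Returns all tested terms (those annotating at least one background gene
    after propagation) with hit counts, raw p and BH-adjusted p, plus an
    ``enriched`` flag for adjusted p <= alpha.
    """
    study = set(study)
    background = set(background)
    if not study:
        raise CrossExprError("empty study set")
    if not study <= background:
        raise CrossExprError("study set must be a subset of the background")
    propagated = propagate_annotations(
        {g: ann.get(g, ()) for g in background}, dag
    )
    term_genes: dict[str, set[str]] = {}
    for gene, terms in propagated.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    big_n, n_draw = len(background), len(study)
    rows = []
    for term, genes in sorted(term_genes.items()):
        hits = len(genes & study)
        pop = len(genes)
        p = float(stats.hypergeom.sf(hits - 1, big_n, pop, n_draw))
        rows.append({"term": term, "name": dag.name(term), "hits": hits, "pop_hits": pop, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched"] = (out["p_adj"] <= alpha) & (out["hits"] > 0)
    return out


# ---------------------------------------------------------------------------
# Wang similarity and BMA
# ---------------------------------------------------------------------------


class WangSimilarity:
    """Wang's graph-based term similarity over a GO DAG, with caching."""

    def __init__(self, dag: GoDag, w_isa: float = 0.8, w_partof: float = 0.6):
        self.dag = dag
        self.weights = {"is_a": w_isa, "part_of": w_partof}
        self._svalues: dict[str, dict[str, float]] = {}

    def s_values(self, term: str) -> dict[str, float]:
        """Max-product path weight from ``term`` to each of its ancestors."""
        if term in self._svalues:
            return self._svalues[term]
        if term not in self.dag.graph:
            raise CrossExprError(f"unknown term {term}")
        sv = {term: 1.0}
        # relax edges repeatedly; DAG guarantees termination in <= depth passes
        frontier = [term]
        while frontier:
            nxt = []
            for t in frontier:
                for parent, rel in self.dag.parents(t):
                    w = self.weights.get(rel, 0.0)
                    cand = sv[t] * w
                    if cand > sv.get(parent, 0.0):
                        sv[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        self._svalues[term] = sv
        return sv

    def sim(self, t1: str, t2: str) -> float:
        s1, s2 = self.s_values(t1), self.s_values(t2)
        common = set(s1) & set(s2)
        if not common:
            return 0.0
        num = sum(s1[a] + s2[a] for a in common)
        den = sum(s1.values()) + sum(s2.values())
        return float(num / den)

    def bma(self, terms_a: Sequence[str], terms_b: Sequence[str]) -> float:
        terms_a, terms_b = list(terms_a), list(terms_b)
        if not terms_a or not terms_b:
            raise CrossExprError("BMA requires two nonempty term sets")
        mat = np.array([[self.sim(a, b) for b in terms_b] for a in terms_a])
        return float((mat.max(axis=1).sum() + mat.max(axis=0).sum()) / (len(terms_a) + len(terms_b)))


def wang_term_similarity(
    t1: str, t2: str, dag: GoDag, w_isa: float = 0.8, w_partof: float = 0.6
) -> float:
    return WangSimilarity(dag, w_isa, w_partof).sim(t1, t2)


def bma_set_similarity(
    terms_a: Sequence[str], terms_b: Sequence[str], dag: GoDag
) -> float:
    return WangSimilarity(dag).bma(terms_a, terms_b)


def ss_permutation_test(
    set_a: Sequence[str],
    set_b: Sequence[str],
    term_pool: Sequence[str],
    dag: GoDag,
    n_perm: int = 1000,
    seed: int = 0,
    sim: WangSimilarity | None = None,
) -> SemSimResult:
    """Observed BMA similarity vs a null of uniformly sampled term sets.

    Each null draw samples |A| and |B| terms without replacement from
    ``term_pool`` and computes their BMA similarity.  Significance is
    one-sided: observed above the null's 95th percentile.
    """
    set_a, set_b = list(set_a), list(set_b)
    pool = list(term_pool)
    if not set_a or not set_b:
        raise CrossExprError("term sets must be nonempty")
    if len(pool) < max(len(set_a), len(set_b)):
        raise CrossExprError("term pool smaller than a term set")
    sim = sim or WangSimilarity(dag)
    observed = sim.bma(set_a, set_b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        ia = rng.choice(len(pool), size=len(set_a), replace=False)
        ib = rng.choice(len(pool), size=len(set_b), replace=False)
        null[i] = sim.bma([pool[j] for j in ia], [pool[j] for j in ib])
    p90, p95 = float(np.percentile(null, 90)), float(np.percentile(null, 95))
    return SemSimResult(
        observed_ss=float(observed),
        null_values=null,
        p90=p90,
        p95=p95,
        significant=bool(observed > p95),
        n_perm=n_perm,
        seed=seed,
    )
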