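"""GO enrichment, Wang similarity, BMA, and the permutation null."""

import itertools

import networkx as nx
import numpy as np
import pytest

from crossexpr import semsim
from crossexpr.semsim import WangSimilarity
from crossexpr.synthdata import GoDag, generate_go_dag
from crossexpr.types import CrossExprError

from conftest import make_matrix


def dag_from_edges(edges, root="R"):
    """Edges are (child, parent, relation)."""
    g = nx.MultiDiGraph()
    g.add_node(root, name=root)
    for c, p, rel in edges:
        g.add_node(c, name=c)
        g.add_node(p, name=p)
        g.add_edge(c, p, key=rel)
    return GoDag(graph=g, root=root)


def brute_force_wang(dag: GoDag, t1: str, t2: str, weights=None) -> float:
    """Independent S-value computation by exhaustive path enumeration."""
    weights = weights or {"is_a": 0.8, "part_of": 0.6}
    plain = nx.DiGraph()
    plain.add_nodes_from(dag.graph.nodes)
    best_edge = {}
    for c, p, rel in dag.graph.edges(keys=True):
        w = weights[rel]
        best_edge[(c, p)] = max(best_edge.get((c, p), 0.0), w)
        plain.add_edge(c, p)

    def s_values(t):
        sv = {t: 1.0}
        for anc in nx.descendants(plain, t):
            best = 0.0
            for path in nx.all_simple_paths(plain, t, anc):
                w = 1.0
                for a, b in zip(path, path[1:]):
                    w *= best_edge[(a, b)]
                best = max(best, w)
            sv[anc] = best
        return sv

    s1, s2 = s_values(t1), s_values(t2)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    return sum(s1[a] + s2[a] for a in common) / (sum(s1.values()) + sum(s2.values()))


class TestTopExpressedGenes:
    def _m(self):
        vals = np.array([[9.0, 9.0], [5.0, 5.0], [5.0, 5.0], [1.0, 1.0]])
        return make_matrix(vals, tissues=["venom_gland"] * 2,
                           genes=["gb", "gc", "ga", "gd"])

    def test_k_one_is_argmax(self):
        assert semsim.top_expressed_genes(self._m(), "venom_gland", k=1) == ["gb"]

    def test_tie_at_cutoff_prefers_smaller_id(self):
        top = semsim.top_expressed_genes(self._m(), "venom_gland", k=2)
        assert top == ["gb", "ga"]

    def test_k_exceeding_gene_count_warns(self):
        with pytest.warns(UserWarning):
            top = semsim.top_expressed_genes(self._m(), "venom_gland", k=10)
        assert len(top) == 4


class TestEnrichTerms:
    def _setup(self):
        # star DAG: 4 leaf terms under the root
        dag = dag_from_edges([(t, "R", "is_a") for t in "ABCD"])
        genes = [f"g{i}" for i in range(20)]
        ann = {g: {"A"} for g in genes[:5]}
        ann.update({g: {"B"} for g in genes[5:]})
        return dag, genes, ann

    def test_exact_hypergeometric_example(self):
        # background 20, term annotates 5, study of 5 contains 4 of them
        dag, genes, ann = self._setup()
        study = genes[:4] + [genes[10]]
        out = semsim.enrich_terms(study, ann, genes, dag).set_index("term")
        assert out.loc["A", "p"] == pytest.approx(76 / 15504)

    def test_universal_term_p_one(self):
        dag, genes, ann = self._setup()
        out = semsim.enrich_terms(genes[:5], ann, genes, dag).set_index("term")
        assert out.loc["R", "p"] == pytest.approx(1.0)  # root annotates everything

    def test_annotations_propagate_to_ancestors(self):
        dag = dag_from_edges([("A", "R", "is_a"), ("B", "A", "part_of")])
        ann = {"g1": {"B"}, "g2": {"A"}, "g3": set()}
        out = semsim.enrich_terms(["g1"], ann, ["g1", "g2", "g3"], dag).set_index("term")
        assert out.loc["A", "pop_hits"] == 2  # B propagated into A
        assert out.loc["R", "pop_hits"] == 2

    def test_null_study_rarely_enriched(self):
        """Uniformly drawn studies produce an enriched term in at most ~5% of
        seeded trials (type-I control at BH 0.05)."""
        dag = generate_go_dag(80, max_depth=6, seed=1)
        rng = np.random.default_rng(2)
        pool = dag.terms
        genes = [f"g{i}" for i in range(200)]
        ann = {
            g: {pool[i] for i in rng.choice(len(pool), size=3, replace=False)}
            for g in genes
        }
        hits = 0
        n_trials = 60
        for _ in range(n_trials):
            study = list(rng.choice(genes, size=30, replace=False))
            out = semsim.enrich_terms(study, ann, genes, dag)
            hits += int(out["enriched"].any())
        assert hits / n_trials <= 0.10

    def test_empty_study_error(self):
        dag, genes, ann = self._setup()
        with pytest.raises(CrossExprError):
            semsim.enrich_terms([], ann, genes, dag)


class TestWangSimilarity:
    def test_self_similarity_one(self):
        dag = dag_from_edges([("A", "R", "is_a")])
        assert semsim.wang_term_similarity("A", "A", dag) == pytest.approx(1.0)

    def test_siblings_under_root(self):
        # S_A = {A: 1, R: 0.8}; sim = (0.8 + 0.8) / (1.8 + 1.8) = 0.444...
        dag = dag_from_edges([("A", "R", "is_a"), ("B", "R", "is_a")])
        assert semsim.wang_term_similarity("A", "B", dag) == pytest.approx(
            1.6 / 3.6
        )

    def test_chain_similarity_decreases_with_distance(self):
        # chain R <- c1 <- c2 <- c3 <- c4
        edges = [("c1", "R", "is_a")] + [
            (f"c{i+1}", f"c{i}", "is_a") for i in range(1, 4)
        ]
        dag = dag_from_edges(edges)
        sims = [semsim.wang_term_similarity("c4", f"c{i}", dag) for i in (3, 2, 1)]
        assert sims[0] > sims[1] > sims[2]

    def test_unknown_term_error(self):
        dag = dag_from_edges([("A", "R", "is_a")])
        with pytest.raises(CrossExprError):
            semsim.wang_term_similarity("A", "nope", dag)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_path_enumeration(self, seed):
        """Wang similarity equals a brute-force all-paths computation on
        random DAGs of up to 8 terms, for every term pair."""
        dag = generate_go_dag(8, max_depth=5, seed=seed)
        sim = WangSimilarity(dag)
        for t1, t2 in itertools.combinations(dag.terms, 2):
            assert sim.sim(t1, t2) == pytest.approx(
                brute_force_wang(dag, t1, t2), abs=1e-12
            )


class TestBmaSetSimilarity:
    def test_identical_sets_one(self):
        dag = dag_from_edges([("A", "R", "is_a"), ("B", "R", "is_a")])
        assert semsim.bma_set_similarity(["A", "B"], ["A", "B"], dag) == pytest.approx(1.0)

    def test_printed_combination(self):
        # {A,B} vs {A}: (1 + 0.444 + 1) / 3 = 0.8148
        dag = dag_from_edges([("A", "R", "is_a"), ("B", "R", "is_a")])
        got = semsim.bma_set_similarity(["A", "B"], ["A"], dag)
        assert got == pytest.approx((1 + 1.6 / 3.6 + 1) / 3)
        assert got == pytest.approx(0.8148, abs=2e-4)

    def test_symmetry(self):
        dag = generate_go_dag(30, seed=3)
        rng = np.random.default_rng(4)
        terms = dag.terms
        a = [terms[i] for i in rng.choice(len(terms), 5, replace=False)]
        b = [terms[i] for i in rng.choice(len(terms), 7, replace=False)]
        assert semsim.bma_set_similarity(a, b, dag) == pytest.approx(
            semsim.bma_set_similarity(b, a, dag)
        )

    def test_empty_set_error(self):
        dag = dag_from_edges([("A", "R", "is_a")])
        with pytest.raises(CrossExprError):
            semsim.bma_set_similarity([], ["A"], dag)


class TestSsPermutationTest:
    def test_set_vs_itself_significant(self):
        dag = generate_go_dag(60, max_depth=6, seed=5)
        terms = dag.terms[10:18]
        res = semsim.ss_permutation_test(terms, terms, dag.terms, dag, n_perm=200, seed=0)
        assert res.observed_ss == pytest.approx(1.0)
        assert res.significant and res.p90 <= res.p95

    def test_same_seed_identical_null(self):
        dag = generate_go_dag(40, seed=6)
        a = semsim.ss_permutation_test(dag.terms[3:6], dag.terms[7:11], dag.terms, dag,
                                       n_perm=50, seed=9)
        b = semsim.ss_permutation_test(dag.terms[3:6], dag.terms[7:11], dag.terms, dag,
                                       n_perm=50, seed=9)
        np.testing.assert_array_equal(a.null_values, b.null_values)

    def test_null_sets_rarely_significant(self):
        """Random term sets exceed the 95th percentile in roughly 5% of
        seeded trials."""
        dag = generate_go_dag(80, max_depth=7, seed=7)
        sim = WangSimilarity(dag)
        rng = np.random.default_rng(8)
        pool = dag.terms
        hits = 0
        n_trials = 60
        for _ in range(n_trials):
            a = [pool[i] for i in rng.choice(len(pool), 6, replace=False)]
            b = [pool[i] for i in rng.choice(len(pool), 6, replace=False)]
            res = semsim.ss_permutation_test(a, b, pool, dag, n_perm=100,
                                             seed=int(rng.integers(2**31)), sim=sim)
            hits += int(res.significant)
        assert hits / n_trials <= 0.12

    def test_pool_too_small_error(self):
        dag = dag_from_edges([("A", "R", "is_a")])
        with pytest.raises(CrossExprError):
            semsim.ss_permutation_test(["A", "R"], ["A"], ["A"], dag)
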