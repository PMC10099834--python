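"""DUG calling, the similarity index, resampling and group tests."""

import numpy as np
import pytest

from crossexpr import diffsim
from crossexpr.diffsim import DUGSets, corrected_si, similarity_index
from crossexpr.synthdata import PlantedProgram, generate_study
from crossexpr.types import CrossExprError

from conftest import make_matrix, small_config


class TestSimilarityIndex:
    def test_printed_formula_value(self):
        # G_T=50, G_A=100, G_B=200 -> 1 - sqrt(0.5 * 0.75) = 0.3876
        a = {f"a{i}" for i in range(100)}
        b = {f"b{i}" for i in range(150)} | set(list(a)[:50])
        duo = DUGSets(a, b)
        assert len(duo.shared) == 50 and len(duo.dugs_b) == 200
        assert similarity_index(duo) == pytest.approx(1 - np.sqrt(0.5 * 0.75))
        assert similarity_index(duo) == pytest.approx(0.3876, abs=5e-5)

    def test_limits_and_symmetry(self):
        full = DUGSets({"x", "y"}, {"x", "y"})
        assert similarity_index(full) == 1.0
        disjoint = DUGSets({"x"}, {"y"})
        assert similarity_index(disjoint) == 0.0
        a, b = {"1", "2", "3"}, {"2", "3", "4", "5"}
        assert similarity_index(DUGSets(a, b)) == similarity_index(DUGSets(b, a))
        assert similarity_index(DUGSets(a, set())) != similarity_index(DUGSets(a, b))

    def test_empty_side_undefined(self):
        assert np.isnan(similarity_index(DUGSets(set(), {"x"})))

    def test_monotone_in_shared_count(self):
        universe = [f"g{i}" for i in range(30)]
        a = set(universe[:10])
        prev = -1.0
        for gt in range(0, 11):
            b = set(universe[:gt]) | set(universe[20 : 30 - gt])
            si = similarity_index(DUGSets(a, b | set(universe[:gt])))
            assert si >= prev
            prev = si


class TestCorrectedSi:
    def test_singleton_families_identity(self):
        a, b = {"g1", "g2"}, {"g2", "g3"}
        fams = {g: f"F_{g}" for g in ("g1", "g2", "g3")}
        assert corrected_si(a, b, fams) == similarity_index(DUGSets(a, b))

    def test_paralogs_raise_shared_count(self):
        a, b = {"a1", "a2"}, {"b1", "b2"}
        fams = {"a1": "F1", "b1": "F1", "a2": "F2", "b2": "F3"}
        # family images: A -> {F1, F2}, B -> {F1, F3}: one shared family
        assert corrected_si(a, b, fams) == pytest.approx(
            similarity_index(DUGSets({"F1", "F2"}, {"F1", "F3"}))
        )

    def test_within_set_paralogs_deduplicate(self):
        a = {"a1", "a2"}
        fams = {"a1": "F1", "a2": "F1", "b1": "F2"}
        assert corrected_si(a, {"b1"}, fams) == 0.0  # G_A collapses to 1 family

    def test_unmapped_gene_error(self):
        with pytest.raises(CrossExprError, match="orthogroup"):
            corrected_si({"gX"}, {"gY"}, {"gY": "F"})

    def test_brute_force_set_image_oracle(self):
        """corrected_si equals an independently coded set-image computation
        on 100 random set systems."""
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(40)]
        for _ in range(100):
            fams = {g: f"F{rng.integers(0, 15)}" for g in genes}
            a = set(rng.choice(genes, size=rng.integers(1, 20), replace=False))
            b = set(rng.choice(genes, size=rng.integers(1, 20), replace=False))
            fa = {fams[g] for g in a}
            fb = {fams[g] for g in b}
            gt, ga, gb = len(fa & fb), len(fa), len(fb)
            expected = 1 - np.sqrt((1 - gt / gb) * (1 - gt / ga))
            assert corrected_si(a, b, fams) == pytest.approx(expected)


class TestCallDugs:
    def _matrix(self, effect=3.0, seed=0, n_genes=120, reps=3):
        rng = np.random.default_rng(seed)
        tissues = (
            ["venom_gland"] * reps + ["ovary"] * reps + ["brain"] * reps
        )
        base = rng.uniform(2, 8, n_genes)
        x = base[:, None] + rng.normal(0, 0.74, (n_genes, 3 * reps))
        x[: n_genes // 2, :reps] += effect  # planted upregulation
        return make_matrix(2.0**x, tissues=tissues, scale="tpm"), n_genes

    def test_identical_groups_ns(self):
        m = make_matrix(np.tile([[4.0], [8.0]], (1, 6)),
                        tissues=["venom_gland"] * 2 + ["ovary"] * 2 + ["brain"] * 2,
                        scale="tpm")
        de = diffsim.call_dugs(m, "venom_gland")
        assert (de.table["direction"] == "ns").all()

    def test_planted_recall_at_effect_three(self):
        """Planted upregulated genes (effect 3, n=3 vs 6, NB-like noise) are
        recalled as 'up' in at least 90% of 100 seeded genes."""
        recalled = 0
        m, n_genes = self._matrix(effect=3.0, seed=1, n_genes=200)
        de = diffsim.call_dugs(m, "venom_gland")
        planted = set(m.gene_ids[: n_genes // 2])
        recalled = len(de.up_genes & planted) / len(planted)
        assert recalled >= 0.9
        # and few false calls
        assert len(de.up_genes - planted) / (n_genes // 2) < 0.1

    def test_fold_change_boundary_strict(self):
        # means chosen so FC = (mean+1)/(mean+1) exactly 2 -> ns
        tissues = ["venom_gland"] * 3 + ["ovary"] * 2 + ["brain"] * 2
        target = [[5.0, 5.2, 4.8]]
        ref = [[2.0, 2.0, 2.0, 2.0]]
        vals = np.hstack([target, ref])
        m = make_matrix(vals, tissues=tissues, scale="tpm")
        fc = (np.mean(target) + 1) / (np.mean(ref) + 1)
        de = diffsim.call_dugs(m, "venom_gland", fc_min=fc)
        assert de.table["direction"].iloc[0] == "ns"
        de2 = diffsim.call_dugs(m, "venom_gland", fc_min=fc - 1e-9)
        assert de2.table["direction"].iloc[0] in ("up", "ns")  # now passes FC gate

    def test_missing_reference_error(self):
        m, _ = self._matrix()
        with pytest.raises(CrossExprError, match="fat_body"):
            diffsim.call_dugs(m, "venom_gland", reference_tissues=("fat_body",))


class TestSiResample:
    @pytest.fixture(scope="class")
    def study(self):
        return generate_study(small_config(seed=21))

    def _ortho_matrix(self, study):
        from crossexpr.pipeline import normalized_ortholog_matrix

        matrix, _ = normalized_ortholog_matrix(study)
        return matrix

    def test_deterministic_and_shared_program_orders_pairs(self, study):
        matrix = self._ortho_matrix(study)
        sub1 = matrix.subset_samples(matrix.sample_ids_where(species="sp01"))
        sub2 = matrix.subset_samples(matrix.sample_ids_where(species="sp02"))
        rep_a = diffsim.si_resample(sub1, "venom_gland", sub2, "silk_gland",
                                    n_reps=20, seed=5)
        rep_b = diffsim.si_resample(sub1, "venom_gland", sub2, "silk_gland",
                                    n_reps=20, seed=5)
        assert rep_a.si_values == rep_b.si_values
        rep_c = diffsim.si_resample(sub1, "venom_gland", sub2, "fat_body",
                                    n_reps=20, seed=5)
        # venom and silk share a planted program; venom and fat body do not
        assert rep_a.median_si > rep_c.median_si

    def test_single_rep_spanning_all_libraries_matches_full_call(self, study):
        matrix = self._ortho_matrix(study)
        sub1 = matrix.subset_samples(matrix.sample_ids_where(species="sp01"))
        n_libs = len(sub1.sample_ids_where(tissue="venom_gland"))
        rep = diffsim.si_resample(sub1, "venom_gland", sub1, "silk_gland",
                                  n_reps=1, libs_per_tissue=n_libs, seed=0)
        de_a = diffsim.call_dugs(sub1, "venom_gland")
        de_b = diffsim.call_dugs(sub1, "silk_gland")
        expected = similarity_index(DUGSets(de_a.up_genes, de_b.up_genes))
        assert rep.si_values[0] == pytest.approx(expected)

    def test_insufficient_libraries_named(self, study):
        matrix = self._ortho_matrix(study)
        sub1 = matrix.subset_samples(matrix.sample_ids_where(species="sp01"))
        with pytest.raises(CrossExprError, match="venom_gland"):
            diffsim.si_resample(sub1, "venom_gland", sub1, "silk_gland",
                                libs_per_tissue=99, n_reps=2, seed=0)


class TestCompareSiGroups:
    def test_exact_mann_whitney_enumeration(self):
        # {1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1
        out = diffsim.compare_si_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert out["U"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        out = diffsim.compare_si_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out["p"].iloc[0] > 0.9
        assert not out["significant"].iloc[0]

    def test_bh_adjustment_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        # and the same convention is applied across group pairs
        groups = {k: list(np.random.default_rng(i).normal(i * 0.2, 1, 10)) for i, k in
                  enumerate(["a", "b", "c", "d"])}
        out = diffsim.compare_si_groups(groups)
        assert (out["fdr"] >= out["p"] - 1e-12).all()

    def test_too_small_group_errors(self):
        with pytest.raises(CrossExprError):
            diffsim.compare_si_groups({"a": [1, 2], "b": [1, 2, 3]})
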