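"""Per-SNP score table, folding, gene aggregation and distance transform."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualclust import (DistanceMatrix, SimilarityMatrix, filter_snps_by_maf,
                       fold_and_maf, gene_similarity, panel_from_dosage,
                       similarity_to_distance, snp_score_table, snp_similarity)
from helpers import similarity_case_oracle


class TestFoldAndMaf:
    def test_no_recode(self):
        g, maf = fold_and_maf(np.array([0, 0, 1, 2]))
        assert maf == pytest.approx(3 / 8)
        assert list(g) == [0, 0, 1, 2]

    def test_folds_major_allele(self):
        g, maf = fold_and_maf(np.array([2, 2, 2, 1]))
        assert list(g) == [0, 0, 0, 1]
        assert maf == pytest.approx(1 / 8)

    def test_monomorphic_excluded(self):
        g, maf = fold_and_maf(np.array([0.0, 0, 0, 0]))
        assert g is None and np.isnan(maf)
        # all-major-homozygote columns fold to constant and are excluded too
        g2, _ = fold_and_maf(np.array([2.0, 2, 2, 2]))
        assert g2 is None

    def test_dosages_round_half_up(self):
        g, _ = fold_and_maf(np.array([0.5, 1.49, 1.5, 0.1]))
        assert list(g) == [1, 1, 2, 0]

    def test_missing_imputed_to_mode(self):
        with pytest.warns(UserWarning, match="imputed"):
            g, _ = fold_and_maf(np.array([0, 0, np.nan, 1]))
        assert list(g) == [0, 0, 0, 1]


class TestSnpSimilarity:
    def test_discordant_homozygotes_value(self):
        assert snp_similarity(0, 2, 0.25) == pytest.approx(-1 / (0.25 * 0.75))

    def test_rare_heterozygote_match_value(self):
        expect = 0.5 * (1 / 0.01 + 1 / 0.81) - 1 / 0.09
        assert snp_similarity(1, 1, 0.1) == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("gi,gj", [(0, 1), (0, 2), (1, 2)])
    def test_symmetric_in_pair(self, gi, gj):
        for p in (0.01, 0.1, 0.37, 0.5):
            assert snp_similarity(gi, gj, p) == snp_similarity(gj, gi, p)

    def test_table_matches_symbolic_oracle_exactly(self):
        """Production table == exact-rational oracle on all 6 cases x 49 MAFs."""
        for k in range(1, 50):
            p = k / 100.0
            table = snp_score_table(p)
            oracle = similarity_case_oracle(Fraction(p))
            for (a, b), val in oracle.items():
                assert table[a, b] == float(val)
                assert table[b, a] == float(val)

    def test_discordant_case_strictly_negative(self):
        assert all(snp_similarity(0, 2, p) < 0 for p in np.linspace(0.001, 0.499, 200))

    def test_minor_match_dominates_major_match_for_rare_snps(self):
        # sharing the rare allele scores high; sharing the common one, near 0
        for p in (0.01, 0.02, 0.05):
            assert snp_similarity(1, 1, p) > snp_similarity(0, 0, p)
            assert snp_similarity(0, 0, p) < 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            snp_similarity(0, 1, 0.0)
        with pytest.raises(ValueError):
            snp_similarity(0, 1, 0.6)
        with pytest.raises(ValueError):
            snp_similarity(0.4, 1, 0.2)
        with pytest.raises(ValueError):
            snp_similarity(3, 1, 0.2)


class TestGeneSimilarity:
    def test_single_snp_gene_matches_scalar(self, toy_panel):
        single = toy_panel.take_snps(np.array([0]))
        single.set_gene_map({"GA": np.array([0])})
        sim = gene_similarity(single, "GA")
        g = single.genotypes[:, 0]
        p = single.maf[0]
        for i in range(6):
            for j in range(6):
                assert sim.values[i, j] == pytest.approx(
                    snp_similarity(g[i], g[j], p), rel=1e-12)

    def test_additive_over_snps(self, toy_panel):
        sim = gene_similarity(toy_panel, "GA")
        parts = []
        for col in toy_panel.gene_map["GA"]:
            sub = toy_panel.take_snps(np.array([col]))
            sub.set_gene_map({"GA": np.array([0])})
            parts.append(gene_similarity(sub, "GA").values)
        np.testing.assert_allclose(sim.values, sum(parts), rtol=1e-12)

    def test_subject_permutation_permutes_rows(self, toy_panel):
        perm = np.array([3, 1, 5, 0, 2, 4])
        shuffled = toy_panel.take_subjects(perm, refold=False)
        s1 = gene_similarity(toy_panel, "GA").values
        s2 = gene_similarity(shuffled, "GA").values
        np.testing.assert_allclose(s2, s1[np.ix_(perm, perm)], rtol=1e-12)

    def test_empty_gene_raises(self, toy_panel):
        with pytest.raises(ValueError, match="no retained SNPs"):
            gene_similarity(toy_panel, "NOPE")


class TestSimilarityToDistance:
    def test_worked_example(self):
        s = np.array([[0.0, 3, 1], [3, 0, -2], [1, -2, 0]])
        d = similarity_to_distance(
            SimilarityMatrix(gene="g", values=s, n_snps_used=1)).values
        assert d[0, 1] == 0 and d[0, 2] == 2 and d[1, 2] == 5

    def test_constant_similarity_all_zero(self):
        s = np.full((4, 4), 7.0)
        d = similarity_to_distance(
            SimilarityMatrix(gene="g", values=s, n_snps_used=1)).values
        assert np.all(d == 0)

    def test_translation_invariance(self, rng):
        s = rng.normal(size=(6, 6))
        s = (s + s.T) / 2
        sm = SimilarityMatrix(gene="g", values=s, n_snps_used=1)
        sm2 = SimilarityMatrix(gene="g", values=s + 13.7, n_snps_used=1)
        np.testing.assert_allclose(similarity_to_distance(sm).values,
                                   similarity_to_distance(sm2).values,
                                   atol=1e-10)

    def test_exponential_transform(self, rng):
        s = rng.normal(size=(5, 5))
        s = (s + s.T) / 2
        sm = SimilarityMatrix(gene="g", values=s, n_snps_used=1)
        d = similarity_to_distance(sm, transform="exponential", lam=0.5).values
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(d[off], np.exp(-0.5 * s[off]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_distance_invariants_random_panels(self, seed):
        r = np.random.default_rng(seed)
        s = r.normal(size=(7, 7))
        s = (s + s.T) / 2
        d = similarity_to_distance(
            SimilarityMatrix(gene="g", values=s, n_snps_used=1))
        v = d.values
        off = ~np.eye(7, dtype=bool)
        assert np.allclose(v, v.T)
        assert np.all(np.diag(v) == 0)
        assert np.all(v[off] >= 0)
        assert v[off].min() == 0.0


class TestMafFilter:
    def test_inclusive_bounds(self):
        mafs = [0.005, 0.01, 0.03, 0.05, 0.2]
        # craft dosage columns whose observed MAF matches `mafs` over 100 subjects
        rng = np.random.default_rng(5)
        n = 100
        cols = []
        for m in mafs:
            c = np.zeros(n)
            c[: int(round(2 * n * m))] = 1  # heterozygotes only
            cols.append(c)
        panel = panel_from_dosage(np.column_stack(cols),
                                  [f"s{i}" for i in range(5)])
        np.testing.assert_allclose(panel.maf, mafs)
        kept = filter_snps_by_maf(panel, 0.01, 0.05)
        assert kept.n_snps == 3

    def test_identity_filter(self, sim_panel):
        assert filter_snps_by_maf(sim_panel, 0.0, 0.5).n_snps == sim_panel.n_snps

    def test_empty_result_permitted(self, sim_panel):
        out = filter_snps_by_maf(sim_panel, 0.4, 0.5)
        assert out.n_snps == 0

    def test_bad_window_rejected(self, sim_panel):
        with pytest.raises(ValueError):
            filter_snps_by_maf(sim_panel, 0.05, 0.01)


def test_distance_matrix_invariants_enforced():
    with pytest.raises(ValueError):
        DistanceMatrix(values=np.array([[0.0, -1], [-1, 0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(values=np.array([[1.0, 2], [2, 1]]))
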