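"""PR's I, one-way ANOVA, permutation p-values, multiplicity, screening."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dualclust import (Partition, SimConfig, adjust_covariates,
                       adjust_multiplicity, anova_oneway, permutation_p, pr_i,
                       screen, simulate_genotypes, simulate_replicates,
                       simulate_traits)
from helpers import anova_f_bruteforce, pr_bruteforce


def _part(labels):
    labels = np.asarray(labels)
    return Partition(labels=labels, k=int(labels.max()))


class TestPrI:
    def test_worked_example_equals_eight(self):
        assert pr_i(np.array([1, 1, 0, 0.0]), _part([1, 1, 2, 2])) == pytest.approx(8.0)

    def test_balanced_means_give_zero(self):
        assert pr_i(np.array([1, 0, 1, 0.0]), _part([1, 1, 2, 2])) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
           st.floats(-10, 10))
    def test_affine_invariance(self, seed, a, b):
        r = np.random.default_rng(seed)
        y = r.normal(size=30)
        labels = r.integers(1, 4, size=30)
        labels[:3] = [1, 2, 3]  # ensure all groups present
        part = _part(labels)
        assert pr_i(a * y + b, part) == pytest.approx(pr_i(y, part), rel=1e-9)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pr_i(np.ones(6), _part([1, 1, 1, 2, 2, 2]))

    def test_normalized_variant_scales_by_n(self, rng):
        y = rng.normal(size=40)
        labels = rng.integers(1, 5, size=40)
        labels[:4] = [1, 2, 3, 4]
        part = _part(labels)
        assert pr_i(y, part, normalize_by_n=True) == pytest.approx(
            pr_i(y, part) / 40, rel=1e-12)


class TestAnova:
    def test_worked_example_f_half(self):
        f, p = anova_oneway(np.array([1, 1, 0, 0, 0, 1.0]),
                            _part([1, 1, 1, 2, 2, 2]))
        assert f == pytest.approx(0.5)
        assert 0 < p <= 1

    def test_two_groups_equals_squared_t(self, rng):
        y = rng.normal(size=24)
        labels = np.repeat([1, 2], 12)
        f, p = anova_oneway(y, _part(labels))
        t = stats.ttest_ind(y[:12], y[12:], equal_var=True)
        assert f == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert p == pytest.approx(t.pvalue, rel=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        for _ in range(20):
            y = rng.normal(size=40)
            labels = rng.integers(1, 5, size=40)
            labels[:4] = [1, 2, 3, 4]
            part = _part(labels)
            f, p = anova_oneway(y, part)
            ref = stats.f_oneway(*(y[labels == g] for g in np.unique(labels)))
            assert f == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_bruteforce_agreement_many_instances(self, rng):
        """I and F match direct group-sum formulas to 1e-10."""
        for _ in range(300):
            n = int(rng.integers(10, 60))
            k = int(rng.integers(2, 6))
            y = rng.normal(size=n)
            labels = rng.integers(1, k + 1, size=n)
            labels[:k] = np.arange(1, k + 1)
            part = _part(labels)
            assert pr_i(y, part) == pytest.approx(
                pr_bruteforce(y, labels), rel=1e-10, abs=1e-10)
            assert anova_oneway(y, part)[0] == pytest.approx(
                anova_f_bruteforce(y, labels), rel=1e-10, abs=1e-10)

    def test_degenerate_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1, 1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            f, p = anova_oneway(y, _part([1, 1, 1, 2, 2, 2]))
        assert np.isinf(f) and 0 < p < 1e-200


class TestPermutationP:
    def test_floor_at_extreme_statistic(self, rng):
        # strong separation: observed beats every permutation
        y = np.r_[np.zeros(20), np.ones(20)]
        part = _part(np.repeat([1, 2], 20))
        p = permutation_p(y, part, stat="pr", B=500, seed=1)
        assert p == pytest.approx(1 / 501)

    def test_same_seed_reproducible(self, rng):
        y = rng.normal(size=30)
        labels = rng.integers(1, 4, size=30)
        labels[:3] = [1, 2, 3]
        part = _part(labels)
        p1 = permutation_p(y, part, stat="anova", B=300, seed=7)
        p2 = permutation_p(y, part, stat="anova", B=300, seed=7)
        assert p1 == p2
        p3 = permutation_p(y, part, stat="anova", B=10_000, seed=8)
        # different seeds agree within Monte Carlo error of the asymptotic p
        assert abs(p3 - anova_oneway(y, part)[1]) < 0.05

    def test_null_uniformity_coarse(self, rng):
        part = _part(np.tile([1, 2, 3, 4], 10))
        ps = [permutation_p(rng.normal(size=40), part, stat="pr", B=199,
                            seed=int(rng.integers(2 ** 31)))
              for _ in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_callable_statistic(self, rng):
        y = rng.normal(size=20)
        part = _part(np.repeat([1, 2], 10))
        p = permutation_p(y, part, stat=lambda yy, pp: pr_i(yy, pp),
                          B=150, seed=3)
        assert 0 < p <= 1

    def test_small_B_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_p(rng.normal(size=10), _part([1, 1, 1, 1, 1, 2, 2, 2, 2, 2]),
                          B=50)


class TestMultiplicity:
    def test_bonferroni_worked_example(self):
        sig, adj = adjust_multiplicity([0.001, 0.04, 0.9], "bonferroni", 0.05)
        assert list(sig) == [True, False, False]
        np.testing.assert_allclose(adj, [0.003, 0.12, 1.0])

    def test_all_ones_nothing_significant(self):
        for method in ("bonferroni", "BH"):
            sig, _ = adjust_multiplicity([1.0, 1.0, 1.0], method, 0.05)
            assert not sig.any()

    def test_bh_step_up(self):
        sig, _ = adjust_multiplicity([0.01, 0.02, 0.03, 0.5], "BH", 0.05)
        assert list(sig) == [True, True, True, False]

    def test_empty_input(self):
        sig, adj = adjust_multiplicity([], "bonferroni", 0.05)
        assert sig.size == 0 and adj.size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            adjust_multiplicity([0.5, np.nan], "bonferroni", 0.05)


@pytest.fixture(scope="module")
def causal_world():
    cfg = SimConfig(n_subjects=300, n_genes=8, snps_per_gene=12,
                    causal_genes=(2,), effect_model="slope", seed=31)
    panel = simulate_genotypes(cfg)
    traits = adjust_covariates(simulate_traits(panel, cfg))
    return cfg, panel, traits


class TestScreen:
    def test_causal_gene_ranks_first(self, causal_world):
        _, panel, traits = causal_world
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = screen(panel, traits, maf_window=(0.0, 0.5), k=10, seed=0)
        assert res.iloc[0]["gene"] == "gene0002"
        assert len(res) == 8

    def test_subject_mismatch_dropped_with_warning(self, causal_world):
        _, panel, traits = causal_world
        truncated = traits.take_subjects(np.arange(250))
        with pytest.warns(UserWarning, match="dropped"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                res = screen(panel, truncated, maf_window=(0.0, 0.5), k=5, seed=0)
        assert len(res) == 8

    def test_disjoint_subjects_fatal(self, causal_world):
        _, panel, traits = causal_world
        import dataclasses
        bad = dataclasses.replace(
            traits, subjects=np.array([f"X{i}" for i in range(traits.n_subjects)]))
        with pytest.raises(ValueError, match="disjoint"):
            screen(panel, bad)

    def test_narrow_window_skips_genes(self, causal_world):
        _, panel, traits = causal_world
        with pytest.warns(UserWarning, match="skipped"):
            res = screen(panel, traits, maf_window=(0.45, 0.5), k=5, seed=0)
        assert len(res) == 0

    def test_null_world_family_wise_error(self):
        """No gene passes Bonferroni at alpha=0.05 in >= 90% of replicates."""
        cfg = SimConfig(n_subjects=200, n_genes=20, snps_per_gene=10,
                        effect_size=0.0, seed=41)
        panel, reps = simulate_replicates(cfg, 10)
        n_clean = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for tp in reps:
                res = screen(panel, adjust_covariates(tp),
                             maf_window=(0.0, 0.5), k=10, seed=1)
                n_clean += not res["significant"].any()
        assert n_clean >= 9
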