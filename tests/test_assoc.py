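"""Association model, BH FDR and the two permutation procedures."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from viropop import (bh_fdr, filter_and_clump, fit_titer_gwas,
                     haplotype_permutation_test, minp_permutation_threshold)
from viropop.assoc import PermutationNull

from conftest import matrix_from_consensus


def _sample_table(n, titer, populations=None, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "sample_id": [f"s{i + 1}" for i in range(n)],
        "population": populations if populations is not None else ["A"] * n,
        "sex": rng.choice(["M", "F"], size=n),
        "infected": True,
        "log10_titer": titer,
    })


def _null_dataset(n=80, n_loci=25, seed=0, populations=None):
    rng = np.random.default_rng(seed)
    calls = (rng.random((n, n_loci)) < rng.uniform(0.2, 0.8, n_loci)).astype(float)
    matrix = matrix_from_consensus(calls)
    titer = rng.normal(4.0, 0.5, n)
    return matrix, _sample_table(n, titer, populations, rng)


class TestFilterAndClump:
    def test_rare_locus_dropped(self):
        calls = np.zeros((10, 2))
        calls[:4, 0] = 1   # 4 carriers < 5
        calls[:6, 1] = 1
        out = filter_and_clump(matrix_from_consensus(calls), min_carriers=5)
        assert list(out.loci.index) == ["L2"]

    def test_identical_columns_within_window_merge(self):
        col = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        m = matrix_from_consensus(np.column_stack([col, col]),
                                  positions=[1000, 6000])
        out = filter_and_clump(m)
        assert list(out.loci.index) == ["L1"]
        assert out.loci.loc["L1", "merged"] == "L2"

    def test_identical_columns_beyond_window_retained(self):
        col = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        m = matrix_from_consensus(np.column_stack([col, col]),
                                  positions=[1000, 16000])
        out = filter_and_clump(m)
        assert list(out.loci.index) == ["L1", "L2"]


class TestBhFdr:
    def bh_oracle(self, p):
        """Textbook step-up: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            q[i] = running
        return q

    @pytest.mark.parametrize("p,expected", [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.5, 0.5, 0.5), (0.5, 0.5, 0.5)),
        ((0.2,), (0.2,)),
    ])
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=6))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_step_up_oracle_on_grid(self, grid):
        p = np.array(grid) * 0.05
        np.testing.assert_allclose(bh_fdr(p), self.bh_oracle(p), atol=1e-12)


class TestFitTiterGwas:
    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(1)
        n = 200
        carrier = (rng.random(n) < 0.5).astype(float)
        noise = (rng.random((n, 10)) < 0.3).astype(float)
        matrix = matrix_from_consensus(np.column_stack([carrier, noise]))
        titer = 3.0 + 2.0 * carrier + rng.normal(0, 0.4, n)
        res = fit_titer_gwas(matrix, _sample_table(n, titer, rng=rng))
        hit = res.loc["L1"]
        assert 1.5 < hit.effect < 2.5
        assert hit.q < 0.01

    def test_null_type_one_error_calibrated(self):
        """Fraction of p < 0.05 under the null within binomial 99% bounds."""
        matrix, samples = _null_dataset(n=100, n_loci=500, seed=2)
        res = fit_titer_gwas(matrix, samples)
        k = (res.p < 0.05).sum()
        lo = stats.binom.ppf(0.005, len(res), 0.05)
        hi = stats.binom.ppf(0.995, len(res), 0.05)
        assert lo <= k <= hi

    def test_constant_locus_skipped(self):
        calls = np.column_stack([np.ones(20), np.tile([0, 1], 10)])
        matrix = matrix_from_consensus(calls)
        titer = np.random.default_rng(3).normal(4, 0.3, 20)
        res = fit_titer_gwas(matrix, _sample_table(20, titer))
        assert "L1" not in res.index and "L2" in res.index

    def test_missing_covariate_named(self):
        matrix, samples = _null_dataset(n=30, n_loci=3)
        with pytest.raises(ValueError, match="wolbachia"):
            fit_titer_gwas(matrix, samples, covariates=("sex", "wolbachia"))

    def test_too_few_infected_rejected(self):
        matrix, samples = _null_dataset(n=8, n_loci=3)
        with pytest.raises(ValueError, match="infected"):
            fit_titer_gwas(matrix, samples)

    def test_agrees_with_statsmodels_ols(self):
        """Cross-check the numpy OLS path against statsmodels on one locus."""
        rng = np.random.default_rng(4)
        n = 60
        f = (rng.random(n) < 0.4).astype(float)
        sex = rng.choice([0.0, 1.0], n)
        titer = 3 + 0.8 * f + 0.1 * sex + rng.normal(0, 0.5, n)
        samples = pd.DataFrame({
            "sample_id": [f"s{i + 1}" for i in range(n)],
            "sex": sex, "infected": True, "log10_titer": titer,
        })
        matrix = matrix_from_consensus(f[:, None])
        res = fit_titer_gwas(matrix, samples, covariates=("sex",),
                             n_relationship_components=0)
        X = sm.add_constant(np.column_stack([f, sex, f * sex]))
        fit = sm.OLS(titer, X).fit()
        assert res.loc["L1", "effect"] == pytest.approx(fit.params[1])
        assert res.loc["L1", "se"] == pytest.approx(fit.bse[1])
        assert res.loc["L1", "p"] == pytest.approx(fit.pvalues[1])


class TestMinPThreshold:
    def test_threshold_is_alpha_quantile_of_constructed_null(self):
        null = PermutationNull(
            n_permutations=1000, statistic="min_p",
            null=0.001 * np.arange(1, 1001), observed=0.0005)
        k = max(1, int(np.floor(0.01 * 1000)))
        assert np.sort(null.null)[k - 1] == pytest.approx(0.01)
        assert 0 < null.empirical_p <= 1

    def test_deterministic_given_seed(self):
        matrix, samples = _null_dataset(n=60, n_loci=10, seed=5)
        t1, n1 = minp_permutation_threshold(matrix, samples, n_perm=200, seed=9)
        t2, n2 = minp_permutation_threshold(matrix, samples, n_perm=200, seed=9)
        assert t1 == t2
        np.testing.assert_array_equal(n1.null, n2.null)

    def test_power_against_planted_haplotype(self):
        """Observed min p beats the threshold in >= 95/100 seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 120
            carrier = (rng.random(n) < 0.5).astype(float)
            noise = (rng.random((n, 14)) < 0.3).astype(float)
            matrix = matrix_from_consensus(np.column_stack([carrier, noise]))
            titer = 3.0 + 2.0 * carrier + rng.normal(0, 0.4, n)
            samples = _sample_table(n, titer, rng=rng)
            threshold, null = minp_permutation_threshold(
                matrix, samples, n_perm=300, seed=seed)
            hits += null.observed < threshold
        assert hits >= 95

    def test_calibrated_rejection_rate_under_null(self):
        """~1% of fresh null datasets fall below the alpha=0.01 threshold."""
        matrix, samples = _null_dataset(n=80, n_loci=20, seed=6)
        threshold, _ = minp_permutation_threshold(matrix, samples,
                                                  n_perm=1000, seed=3)
        rejections = 0
        n_datasets = 500
        for seed in range(n_datasets):
            m, s = _null_dataset(n=80, n_loci=20, seed=10_000 + seed)
            res = fit_titer_gwas(m, s)
            rejections += res.p.min() < threshold
        lo = stats.binom.ppf(0.005, n_datasets, 0.01)
        hi = stats.binom.ppf(0.995, n_datasets, 0.01)
        assert lo <= rejections <= hi


class TestHaplotypePermutation:
    def _planted(self, seed=0, n=120, sd=0.3):
        rng = np.random.default_rng(seed)
        carrier = (rng.random(n) < 0.5).astype(float)
        block = np.tile(carrier[:, None], (1, 11))
        noise = (rng.random((n, 8)) < 0.3).astype(float)
        matrix = matrix_from_consensus(np.column_stack([block, noise]))
        titer = 3.0 + 2.0 * carrier + rng.normal(0, sd, n)
        return matrix, _sample_table(n, titer, rng=rng)

    def test_constant_titer_gives_p_one(self):
        matrix, samples = self._planted(seed=1)
        samples["log10_titer"] = 4.0
        null = haplotype_permutation_test(matrix, samples, n_perm=50, seed=2)
        assert null.observed == 0.0
        assert null.empirical_p == 1.0

    def test_planted_haplotype_reaches_floor_p(self):
        matrix, samples = self._planted(seed=3)
        null = haplotype_permutation_test(matrix, samples, n_perm=300, seed=4)
        assert null.empirical_p == pytest.approx(1 / 301)

    def test_fixed_focal_requires_locus(self):
        matrix, samples = self._planted(seed=5)
        with pytest.raises(ValueError, match="focal_locus"):
            haplotype_permutation_test(matrix, samples, mode="fixed_focal")

    def test_fixed_focal_mode_matches_planted_locus(self):
        matrix, samples = self._planted(seed=6)
        null = haplotype_permutation_test(
            matrix, samples, n_perm=200, seed=7, mode="fixed_focal",
            focal_locus="L1")
        assert null.empirical_p == pytest.approx(1 / 201)

    def test_within_population_permutation_respects_stratification(self):
        """A purely population-driven titer signal looks less surprising
        when permutations preserve population membership."""
        rng = np.random.default_rng(8)
        n = 120
        pops = np.array(["A"] * 60 + ["B"] * 60)
        block = np.tile((pops == "B").astype(float)[:, None], (1, 11))
        noise = (rng.random((n, 8)) < 0.3).astype(float)
        matrix = matrix_from_consensus(np.column_stack([block, noise]))
        titer = 3.0 + 1.0 * (pops == "B") + rng.normal(0, 0.3, n)
        samples = _sample_table(n, titer, populations=pops, rng=rng)
        kwargs = dict(n_perm=200, mode="fixed_focal", focal_locus="L1",
                      covariates=("sex",), n_relationship_components=0)
        within = haplotype_permutation_test(
            matrix, samples, seed=9, stratify_by_population=True, **kwargs)
        across = haplotype_permutation_test(
            matrix, samples, seed=9, stratify_by_population=False, **kwargs)
        assert within.empirical_p > across.empirical_p

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_empirical_p_never_zero(self, seed):
        rng = np.random.default_rng(seed)
        null = PermutationNull(
            n_permutations=20, statistic="high_low_difference",
            null=rng.normal(size=20), observed=float(rng.normal()))
        assert 0 < null.empirical_p <= 1
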