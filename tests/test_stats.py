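"""GLM contrasts, permutation nulls, pooled t, Hedges g, adjusted association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tbinet import stats

from conftest import make_cohort_table


def classical_pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook pooled-variance two-sample t (independent oracle)."""
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestGlmContrast:
    def _design(self, n1, n2):
        groups = np.r_[np.ones(n1), np.zeros(n2)]
        return stats.DesignMatrix(
            np.column_stack([groups, 1 - groups]), ["control", "tbi"]
        )

    def test_matches_classical_pooled_t_without_covariates(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(5, 20, 2)
            y = rng.standard_normal(n1 + n2)
            t, _, df = stats.glm_contrast_ttest(y, self._design(n1, n2), [1, -1])
            expected = classical_pooled_t(y[:n1], y[n1:])
            assert t[0] == pytest.approx(expected, abs=1e-10)
            assert df == n1 + n2 - 2

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        cohort = make_cohort_table(10, 8)
        y = rng.standard_normal(18)
        design = stats.design_from_cohort(cohort, ("age", "fd_mean"))
        t, p, _ = stats.glm_contrast_ttest(y, design, [1, -1])
        fit = sm.OLS(y, design.matrix).fit()
        tt = fit.t_test(np.array([1.0, -1.0, 0.0, 0.0]))
        assert t[0] == pytest.approx(float(np.ravel(tt.tvalue)[0]), abs=1e-8)
        assert p[0] == pytest.approx(float(np.ravel(tt.pvalue)[0]), abs=1e-8)

    def test_zero_contrast_gives_t0_p1(self, rng):
        y = rng.standard_normal(12)
        t, p, _ = stats.glm_contrast_ttest(y, self._design(6, 6), [0, 0])
        assert t[0] == 0 and p[0] == 1

    def test_confound_driven_group_difference_removed_by_adjustment(self):
        rng = np.random.default_rng(2)
        cohort = make_cohort_table(15, 10)
        # make age itself differ between groups, and y depend only on age:
        # the unadjusted group test fires, the age-adjusted one does not
        cohort.loc[cohort["group"] == "tbi", "age"] += 6.0
        y = 2.0 * cohort["age"].to_numpy() + 0.3 * rng.standard_normal(25)
        raw_design = stats.design_from_cohort(cohort, ())
        adj_design = stats.design_from_cohort(cohort, ("age",))
        t_raw, _, _ = stats.glm_contrast_ttest(y, raw_design, [1, -1])
        t_adj, _, _ = stats.glm_contrast_ttest(y, adj_design, [1, -1])
        assert abs(t_raw[0]) > 3
        assert abs(t_adj[0]) < 2

    def test_contrast_negation_flips_t_keeps_p(self, rng):
        y = rng.standard_normal((14, 3))
        d = self._design(7, 7)
        t1, p1, _ = stats.glm_contrast_ttest(y, d, [1, -1])
        t2, p2, _ = stats.glm_contrast_ttest(y, d, [-1, 1])
        assert np.allclose(t1, -t2) and np.allclose(p1, p2)

    def test_rank_deficient_design_names_columns(self):
        x = np.column_stack([np.ones(10), np.ones(10)])
        d = stats.DesignMatrix(x, ["control", "tbi"])
        with pytest.raises(ValueError, match="rank deficient"):
            stats.glm_contrast_ttest(np.arange(10.0), d, [1, -1])


class TestPermutationPvalue:
    def test_constant_statistic_gives_p1(self):
        labels = np.r_[np.ones(5), np.zeros(5)]
        p = stats.permutation_pvalue(lambda lbl: 3.14, labels, n_perm=99, seed=0)
        assert p[0] == 1.0

    def test_huge_effect_attains_minimum(self):
        rng = np.random.default_rng(3)
        y = np.r_[rng.standard_normal(20) + 10, rng.standard_normal(20)]
        labels = np.r_[np.ones(20), np.zeros(20)]

        def stat(lbl):
            return y[lbl == 1].mean() - y[lbl == 0].mean()

        n_perm = 200
        p = stats.permutation_pvalue(stat, labels, n_perm=n_perm, seed=0)
        assert p[0] == pytest.approx(1 / (n_perm + 1))

    def test_null_calibration(self):
        # empirical rejection at alpha=0.05 under a true null
        rejections = 0
        reps = 200
        labels = np.r_[np.ones(12), np.zeros(10)]
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            y = rng.standard_normal(22)

            def stat(lbl):
                return y[lbl == 1].mean() - y[lbl == 0].mean()

            p = stats.permutation_pvalue(stat, labels, n_perm=99, seed=rep + 1)
            rejections += p[0] < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_monotone_transform_invariance(self, rng):
        y = rng.standard_normal(16)
        labels = np.r_[np.ones(8), np.zeros(8)]

        def stat(lbl):
            return y[lbl == 1].mean() - y[lbl == 0].mean()

        p1 = stats.permutation_pvalue(stat, labels, n_perm=150, seed=5)
        p2 = stats.permutation_pvalue(
            lambda lbl: np.abs(stat(lbl)) ** 3, labels, n_perm=150, seed=5
        )
        assert p1[0] == p2[0]

    def test_deterministic_given_seed(self, rng):
        y = rng.standard_normal(10)
        labels = np.r_[np.ones(5), np.zeros(5)]
        stat = lambda lbl: y[lbl == 1].sum()
        a = stats.permutation_pvalue(stat, labels, n_perm=50, seed=9)
        b = stats.permutation_pvalue(stat, labels, n_perm=50, seed=9)
        assert a[0] == b[0]

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            stats.permutation_pvalue(lambda l: 0.0, np.ones(4), n_perm=0)


class TestPooledT:
    def test_printed_balance_summaries(self):
        # the static-balance group summaries reproduce the printed statistic
        t = stats.pooled_two_sample_t(106.72, 8.41, 27, 88.63, 28.80, 14)
        assert t == pytest.approx(3.054, abs=0.01)

    def test_equal_means_zero(self):
        assert stats.pooled_two_sample_t(5, 1, 10, 5, 2, 10) == 0.0
        assert stats.pooled_two_sample_t(5, 0, 10, 5, 0, 10) == 0.0

    def test_zero_variance_unequal_means_errors(self):
        with pytest.raises(ValueError, match="infinite"):
            stats.pooled_two_sample_t(5, 0, 10, 6, 0, 10)

    def test_matches_raw_data_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(9) * 3 + 1, rng.standard_normal(7)
        from_summaries = stats.pooled_two_sample_t(
            a.mean(), a.std(ddof=1), 9, b.mean(), b.std(ddof=1), 7
        )
        assert from_summaries == pytest.approx(classical_pooled_t(a, b), abs=1e-12)


class TestHedgesG:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (2.6351, 0.8511),
            (3.1276, 1.0101),
            (-2.7511, -0.8885),
            (3.4186, 1.1041),
            (-2.5512, -0.8240),
        ],
    )
    def test_printed_effect_sizes(self, t, expected):
        # agreement at the 4th decimal place: within one unit of the last
        # printed digit (the published table was computed from unrounded t)
        g, _ = stats.hedges_g(t, 27, 14)
        assert abs(g - expected) <= 1e-4

    def test_zero_t_zero_g(self):
        g, (lo, hi) = stats.hedges_g(0.0, 27, 14)
        assert g == 0.0 and lo < 0 < hi

    def test_odd_in_t(self, rng):
        for t in rng.standard_normal(10) * 3:
            g1, _ = stats.hedges_g(t, 12, 9)
            g2, _ = stats.hedges_g(-t, 12, 9)
            assert g1 == pytest.approx(-g2)

    def test_ci_contains_g(self, rng):
        g, (lo, hi) = stats.hedges_g(2.0, 20, 15)
        assert lo < g < hi


class TestAdjustedAssociation:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        out = stats.adjusted_association(x, 2 * x)
        assert out["r"] == pytest.approx(1.0) and out["s"] == pytest.approx(1.0)

    def test_cubic_rank_preserved_linearity_lost(self):
        x = np.linspace(-3, 3, 21)
        out = stats.adjusted_association(x, x**3)
        assert out["s"] == pytest.approx(1.0)
        assert out["r"] < 1.0

    def test_planted_partial_correlation_recovery(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = 200
            age = rng.uniform(8, 19, n)
            true_r = 0.8
            zx, zy = rng.standard_normal((2, n))
            x = 0.5 * age + zx
            y = 0.7 * age + true_r * zx + np.sqrt(1 - true_r**2) * zy
            out = stats.adjusted_association(x, y, covariates=age)
            hits += 0.7 <= out["r"] <= 0.9
        assert hits >= 23

    def test_imaging_only_residualization_mode(self, rng):
        n = 50
        cov = rng.standard_normal(n)
        x = cov + 0.1 * rng.standard_normal(n)
        y = rng.standard_normal(n)
        both = stats.adjusted_association(x, y, covariates=cov, residualize="both")
        xonly = stats.adjusted_association(x, y, covariates=cov, residualize="x_only")
        assert both["r"] != xonly["r"]

    def test_zero_variance_residuals_error(self):
        cov = np.arange(10.0)
        with pytest.raises(ValueError, match="residual"):
            stats.adjusted_association(2 * cov, cov**2, covariates=cov)


class TestGroupComparisonTable:
    def test_flipping_groups_negates_t(self):
        cohort = make_cohort_table(10, 8, seed=1)
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.standard_normal((18, 3)), index=cohort.index, columns=list("abc")
        )
        flipped = cohort.copy()
        flipped["group"] = np.where(flipped["group"] == "control", "tbi", "control")
        t1 = stats.group_comparison_table(vals, cohort, n_perm=20, seed=0)["t"]
        t2 = stats.group_comparison_table(vals, flipped, n_perm=20, seed=0)["t"]
        assert np.allclose(t1.to_numpy(), -t2.to_numpy())

    def test_scaling_descriptor_leaves_t_unchanged(self):
        cohort = make_cohort_table(9, 7, seed=2)
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.standard_normal((16, 2)), index=cohort.index)
        a = stats.group_comparison_table(vals, cohort, n_perm=20, seed=3)
        b = stats.group_comparison_table(vals * 37.5, cohort, n_perm=20, seed=3)
        assert np.allclose(a["t"], b["t"]) and np.allclose(a["p_perm"], b["p_perm"])
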