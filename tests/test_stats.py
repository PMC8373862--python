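import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from digitcoord import (
    learning_rate,
    normalized_improvement,
    normalized_improvement_compare,
    paired_t,
    pearson,
    rm_anova,
    signed_rank,
)


def _brute_force_rm_anova(data):
    """Plain-loop sums-of-squares decomposition as an independent oracle."""
    n, k = data.shape
    grand = sum(data[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_subj = sum(k * (sum(data[i]) / k - grand) ** 2 for i in range(n))
    ss_cond = sum(n * (sum(data[i][j] for i in range(n)) / n - grand) ** 2 for j in range(k))
    ss_tot = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_subj - ss_cond
    f = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    eta = ss_cond / (ss_cond + ss_err)
    return f, eta


class TestRmAnova:
    def test_identical_conditions_give_zero_effect(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 4)) + 1.0
        res = rm_anova(data)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.partial_eta_sq == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_decomposition(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1, (6, 3)) + rng.normal(0, 1, (6, 1))
        res = rm_anova(data)
        f, eta = _brute_force_rm_anova(data)
        assert res.F == pytest.approx(f, abs=1e-8)
        assert res.partial_eta_sq == pytest.approx(eta, abs=1e-8)

    def test_two_conditions_need_no_sphericity(self):
        rng = np.random.default_rng(1)
        res = rm_anova(rng.normal(0, 1, (8, 2)))
        assert res.gg_epsilon == 1.0
        assert not res.corrected
        # with k=2 the rmANOVA is the squared paired t
        a, b = rng.normal(0, 1, (2, 8))
        res2 = rm_anova(np.column_stack([a, b]))
        t = sp_stats.ttest_rel(a, b)
        assert res2.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res2.p == pytest.approx(t.pvalue, rel=1e-10)

    def test_epsilon_within_theoretical_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = rng.integers(3, 6)
            data = rng.normal(0, rng.uniform(0.2, 2.0, k), (7, k))
            res = rm_anova(data)
            assert 1.0 / (k - 1) - 1e-12 <= res.gg_epsilon <= 1.0 + 1e-12

    def test_agrees_with_pingouin_including_correction(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, k = int(rng.integers(5, 10)), int(rng.integers(3, 6))
            data = rng.normal(0, rng.uniform(0.2, 2.0, k), (n, k)) + rng.normal(0, 1, (n, 1))
            res = rm_anova(data)
            df = pd.DataFrame(data).reset_index().melt("index", var_name="c", value_name="y")
            aov = pg.rm_anova(
                data=df, dv="y", within="c", subject="index", correction=True, effsize="np2"
            )
            sph = pg.sphericity(data=df, dv="y", within="c", subject="index")
            assert res.F == pytest.approx(aov.loc[0, "F"], abs=1e-8)
            assert res.gg_epsilon == pytest.approx(aov.loc[0, "eps"], abs=1e-8)
            assert res.partial_eta_sq == pytest.approx(aov.loc[0, "np2"], abs=1e-8)
            assert res.mauchly_p == pytest.approx(sph.pval, abs=1e-8)
            expected_p = aov.loc[0, "p_GG_corr"] if not sph.spher else aov.loc[0, "p_unc"]
            assert res.p == pytest.approx(expected_p, abs=1e-8)

    def test_missing_cells_rejected(self):
        data = np.ones((4, 3))
        data[1, 2] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova(data)


class TestPairedT:
    def test_bonferroni_threshold(self):
        rng = np.random.default_rng(5)
        res = paired_t(rng.normal(0, 1, 12), rng.normal(0, 1, 12), family_m=4)
        assert res.alpha_adjusted == pytest.approx(0.0125)
        assert res.df == 11

    def test_zero_variance_differences_flagged(self):
        a = np.arange(6.0)
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t(a, a + 2.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        a = rng.normal(1.0, 0.5, 12)
        b = rng.normal(0.8, 0.5, 12)
        res = paired_t(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        p = 2 * sp_stats.t.sf(abs(t), 11)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.d == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-12)

    def test_avg_sd_effect_size_variant(self):
        rng = np.random.default_rng(7)
        a = rng.normal(1, 1, 10)
        b = rng.normal(0, 1, 10)
        res = paired_t(a, b, d_variant="avg_sd")
        pooled = np.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2)
        assert res.d == pytest.approx((a - b).mean() / pooled, abs=1e-12)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 12)
        y = 0.5 * x + rng.normal(0, 1, 12)
        res = pearson(x, y)
        r = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.n == 12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance|zero-variance"):
            pearson(np.ones(5), np.arange(5.0))


class TestSignedRank:
    def test_all_positive_differences_reach_rank_sum_maximum(self):
        # n = 12, every a > b: T+ = 78, z = (78 - 39) / sqrt(12*13*25/24)
        a = np.arange(1.0, 13.0)
        b = a - np.linspace(0.5, 6.0, 12)
        res = signed_rank(a, b)
        z_exact = (78 - 39) / np.sqrt(12 * 13 * 25 / 24)
        assert res.z == pytest.approx(z_exact, abs=1e-12)
        assert res.n == 12

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.3, 1, 15)
        b = rng.normal(0.0, 1, 15)
        res = signed_rank(a, b)
        ref = sp_stats.wilcoxon(a, b, zero_method="wilcox", correction=False, method="approx")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert abs(res.z) == pytest.approx(abs(ref.zstatistic), abs=1e-10)

    def test_all_zero_differences_is_an_error(self):
        a = np.ones(6)
        with pytest.raises(ValueError, match="zero"):
            signed_rank(a, a)


class TestImprovementComparison:
    def test_proportional_normalization(self):
        imp = normalized_improvement([1.0, 2.0], [0.5, 1.5])
        np.testing.assert_allclose(imp, [0.5, 0.25])

    def test_greater_speed_improvement_detected(self):
        rng = np.random.default_rng(10)
        n = 12
        cyc1 = rng.uniform(0.9, 1.1, n)
        cyc5 = cyc1 * rng.uniform(0.75, 0.85, n)  # ~20% faster by block 5
        crd1 = rng.uniform(0.10, 0.14, n)
        crd5 = crd1 * rng.uniform(0.97, 1.03, n)  # no coordination change
        res = normalized_improvement_compare((cyc1, cyc5), (crd1, crd5))
        assert res.z > 0
        assert res.p < 0.01

    def test_identical_metrics_error_path(self):
        vals = (np.array([1.0, 2.0, 3.0]), np.array([0.5, 1.0, 1.5]))
        with pytest.raises(ValueError, match="zero"):
            normalized_improvement_compare(vals, vals)


class TestLearningRate:
    def test_sequence_and_mapping_inputs(self):
        assert learning_rate([1.0, 0.9, 0.8, 0.7, 0.6]) == pytest.approx(0.4)
        assert learning_rate({1: 0.5, 5: 0.5}) == pytest.approx(0.0)

    def test_missing_block_rejected(self):
        with pytest.raises(ValueError, match="blocks 1 and 5"):
            learning_rate({1: 0.5, 4: 0.4})
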