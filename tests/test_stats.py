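"""Regression, outlier treatment, agreement and power statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from nocimec import (
    PowerSpec,
    RegressionFit,
    bland_altman,
    bonferroni,
    grubbs_test,
    iterative_outlier_regression,
    pearson_test,
    power_sample_size,
    predict_rocbp,
    substitute_out_of_range,
)
from nocimec.stats import grubbs_critical


def pearson_oracle(x, y):
    """Closed-form product-moment r and its two-sided t-test p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    return r, 2 * sps.t.sf(abs(t), n - 2)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonal_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # uncorrelated with x by symmetry
        r, _ = pearson_test(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = pearson_test(x, y)
        r0, p0 = pearson_oracle(x, y)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected",
                             [(0.009, 4, 0.036), (0.5, 4, 1.0), (0.0, 7, 0.0)])
    def test_multiply_and_cap(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_idempotent_at_cap(self, p1, p2):
        lo, hi = sorted([p1, p2])
        assert bonferroni(lo) <= bonferroni(hi)
        assert bonferroni(bonferroni(p1, 4), 1) == bonferroni(p1, 4)


class TestGrubbs:
    def test_gross_outlier_flagged(self):
        out = grubbs_test([1.0, 2.0, 3.0, 4.0, 100.0])
        assert out.flagged_index == 4
        assert out.statistic > out.critical_value

    def test_clean_sequence_not_flagged(self):
        out = grubbs_test([1.0, 2.0, 3.0, 4.0, 5.0])
        assert out.statistic == pytest.approx(1.2649, abs=1e-4)
        assert out.flagged_index is None

    def test_constant_list_degenerate(self):
        out = grubbs_test([3.0, 3.0, 3.0, 3.0])
        assert out.statistic == 0.0 and out.flagged_index is None

    @pytest.mark.parametrize("n,expected", [(5, 1.715), (10, 2.290), (20, 2.709)])
    def test_critical_values_match_published_table(self, n, expected):
        """Two-sided 5% single-outlier critical values (standard tables)."""
        assert grubbs_critical(n) == pytest.approx(expected, abs=2e-3)

    def test_agrees_with_max_deviation_scan(self):
        """G equals the largest studentised deviation found by brute force."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            v = rng.normal(size=rng.integers(3, 9))
            out = grubbs_test(v)
            devs = np.abs(v - v.mean()) / v.std(ddof=1)
            assert out.statistic == pytest.approx(devs.max(), abs=1e-12)
            if out.flagged_index is not None:
                assert out.flagged_index == int(np.argmax(devs))


class TestIterativeRegression:
    def test_perfect_line_no_removals(self):
        x = np.arange(10.0)
        fit = iterative_outlier_regression(x, -0.3 * x + 5.0)
        assert fit.iterations == 0
        assert fit.slope == pytest.approx(-0.3)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.n_used == 10

    def test_gross_outlier_removed_and_slope_recovered(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(10, 80, 20)
        y = -0.3 * x + 30 + rng.normal(0, 1.0, 20)
        y[7] += 50.0
        fit = iterative_outlier_regression(x, y)
        assert 7 in fit.removed_ids
        assert abs(fit.slope / -0.3 - 1) < 0.05

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(10, 80, 15)
        y = -0.3 * x + 30 + rng.normal(0, 2.0, 15)
        y[3] += 40.0
        ids = [f"S{i}" for i in range(15)]
        fit1 = iterative_outlier_regression(x, y, ids=ids)
        perm = rng.permutation(15)
        fit2 = iterative_outlier_regression(x[perm], y[perm],
                                            ids=[ids[i] for i in perm])
        assert sorted(fit1.removed_ids) == sorted(fit2.removed_ids)
        assert fit1.slope == pytest.approx(fit2.slope, rel=1e-12)
        assert fit1.intercept == pytest.approx(fit2.intercept, rel=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            iterative_outlier_regression([1, 2, 3], [1, 2, 3])

    def test_coverage_of_analytic_confidence_intervals(self):
        """Fitted slope/intercept fall in their analytic 95% CIs in >=90%
        of clean replicates (n = 30, sigma = 5)."""
        rng = np.random.default_rng(42)
        hits_slope = hits_int = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.choice(np.arange(10.0, 90.0, 10.0), 30)
            y = -0.28 * x + 31.26 + rng.normal(0, 5.0, 30)
            res = sps.linregress(x, y)
            tcrit = sps.t.ppf(0.975, 28)
            hits_slope += abs(res.slope - (-0.28)) <= tcrit * res.stderr
            hits_int += abs(res.intercept - 31.26) <= tcrit * res.intercept_stderr
        assert hits_slope / n_rep >= 0.90
        assert hits_int / n_rep >= 0.90


class TestSubstitutionAndPrediction:
    FIT = RegressionFit(-0.28, 31.26, -0.723, 1e-4, 27, [], 0)

    def test_printed_equation_inversion(self):
        assert substitute_out_of_range(self.FIT, [0.7]) == pytest.approx(109.1, abs=0.05)

    def test_root_at_origin(self):
        fit = RegressionFit(-0.28, 31.26, 0, 0, 5, [], 0)
        assert substitute_out_of_range(fit, [31.26]) == pytest.approx(0.0)

    def test_unit_slope(self):
        fit = RegressionFit(-1.0, 0.0, 0, 0, 5, [], 0)
        assert substitute_out_of_range(fit, [-40.0]) == pytest.approx(40.0)

    def test_zero_slope_rejected(self):
        fit = RegressionFit(0.0, 1.0, 0, 0, 5, [], 0)
        with pytest.raises(ValueError):
            substitute_out_of_range(fit, [1.0])

    def test_predict_printed_equations(self):
        assert predict_rocbp(self.FIT, 50.0) == pytest.approx(17.26)
        fit5 = RegressionFit(0.05, 13.25, 0.441, 0.017, 27, [], 0)
        assert predict_rocbp(fit5, 135.0) == pytest.approx(20.0)

    def test_flat_model_returns_intercept(self):
        fit = RegressionFit(0.0, 4.2, 0, 0, 5, [], 0)
        assert predict_rocbp(fit, 123.0) == 4.2

    def test_roundtrip_identity(self):
        """predict ∘ substitute returns the mean out-of-range ROC_BP."""
        oor = [-3.7, 2.6, 3.3]
        mec = substitute_out_of_range(self.FIT, oor)
        assert predict_rocbp(self.FIT, mec) == pytest.approx(np.mean(oor), abs=1e-12)


class TestBlandAltman:
    def test_identity_vectors(self):
        v = [1.0, 2.0, 3.0]
        rep = bland_altman(v, v)
        assert rep.fixed_bias == 0.0
        assert rep.loa_high - rep.loa_low == 0.0

    def test_constant_offset(self):
        m = np.array([5.0, 7.0, 9.0])
        rep = bland_altman(m, m - 2.0)
        assert rep.fixed_bias == pytest.approx(2.0)
        assert rep.loa_low == rep.loa_high == pytest.approx(2.0)

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(9)
        m, p = rng.normal(20, 5, 30), rng.normal(20, 5, 30)
        rep = bland_altman(m, p)
        d = m - p
        assert rep.fixed_bias == pytest.approx(d.mean(), abs=1e-12)
        assert rep.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
        assert rep.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)
        r0, p0 = pearson_oracle(d, (m + p) / 2)
        assert rep.proportional_r == pytest.approx(r0, abs=1e-12)
        assert rep.proportional_p == pytest.approx(p0, abs=1e-12)

    def test_degenerate_means_reported_not_applicable(self):
        rep = bland_altman([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])  # means constant
        assert rep.proportional_r is None


class TestPower:
    def test_reproduces_study_sample_size(self):
        assert power_sample_size(PowerSpec(0.5, 0.05, 0.8)) == 26

    def test_weaker_correlation(self):
        assert power_sample_size(PowerSpec(0.3, 0.05, 0.8)) == 82

    def test_non_increasing_in_r(self):
        ns = [power_sample_size(PowerSpec(r)) for r in (0.2, 0.4, 0.6, 0.8)]
        assert ns == sorted(ns, reverse=True)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            power_sample_size(PowerSpec(1.5))
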