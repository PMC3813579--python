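"""Unit and property tests for the logistic-regression engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, kstest

from supramult.regression import (
    CollinearityError,
    DegeneratePhenotypeError,
    DesignMatrix,
    TestResult,
    fit_logistic,
    likelihood_ratio_test,
    wald_test,
)


def _dm(n, **cols):
    return DesignMatrix.from_columns(n, cols)


class TestDesignMatrix:
    def test_requires_intercept_first(self):
        with pytest.raises(ValueError, match="intercept"):
            DesignMatrix(np.array([[2.0, 1.0]]), ("a", "b"))

    def test_rejects_non_finite_and_duplicate_labels(self):
        with pytest.raises(ValueError, match="non-finite"):
            _dm(2, x=np.array([1.0, np.nan]))
        with pytest.raises(ValueError, match="unique"):
            DesignMatrix(np.ones((2, 2)), ("a", "a"))


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        y = np.array([0, 1, 0, 1], dtype=float)
        fit = fit_logistic(_dm(4), y)
        assert fit.converged
        assert fit.coefficient("intercept") == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_three_quarters(self):
        y = np.array([1, 1, 1, 0] * 5, dtype=float)
        fit = fit_logistic(_dm(20), y)
        assert fit.coefficient("intercept") == pytest.approx(np.log(3), abs=1e-8)

    def test_matches_independent_oracle(self, small_logistic_data):
        """Coefficients agree with statsmodels' independent Newton fit to 1e-6."""
        sm = pytest.importorskip("statsmodels.api")
        x1, x2, y = small_logistic_data
        fit = fit_logistic(_dm(20, x1=x1, x2=x2), y)
        X = np.column_stack([np.ones(20), x1, x2])
        oracle = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-12)
        np.testing.assert_allclose(fit.coefficients, oracle.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, oracle.bse, rtol=1e-4)
        assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-8)

    def test_degenerate_phenotype(self):
        with pytest.raises(DegeneratePhenotypeError, match="degenerate"):
            fit_logistic(_dm(5), np.ones(5))

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = (rng.random(30) < 0.5).astype(float)
        with pytest.raises(CollinearityError) as err:
            fit_logistic(_dm(30, x=x, x_copy=2 * x), y)
        assert "x_copy" in str(err.value) or "x" in str(err.value)

    def test_separation_flagged(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = np.array([0.0] * 10 + [1.0] * 10)
        fit = fit_logistic(_dm(20, x=x), y)
        assert fit.separation_flag
        with pytest.raises(ValueError, match="unreliable Wald"):
            wald_test(fit, "x")

    def test_loglikelihood_nonpositive(self, small_logistic_data):
        x1, x2, y = small_logistic_data
        fit = fit_logistic(_dm(20, x1=x1, x2=x2), y)
        assert fit.log_likelihood <= 0.0
        assert (fit.standard_errors > 0).all()


class TestLikelihoodRatio:
    def test_identical_models_give_p_one(self, small_logistic_data):
        x1, x2, y = small_logistic_data
        fit = fit_logistic(_dm(20, x1=x1), y)
        res = likelihood_ratio_test(fit, fit, 1)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize(
        "stat, df, expected",
        [(3.841459, 1, 0.0500), (20.09, 8, 0.0100)],
    )
    def test_chi_square_tail(self, stat, df, expected):
        assert chi2.sf(stat, df) == pytest.approx(expected, abs=1e-4)

    def test_invalid_df(self, small_logistic_data):
        x1, x2, y = small_logistic_data
        fit = fit_logistic(_dm(20, x1=x1), y)
        with pytest.raises(ValueError, match="positive integer"):
            likelihood_ratio_test(fit, fit, 0)

    def test_non_nested_rejected(self, small_logistic_data):
        x1, x2, y = small_logistic_data
        f_big = fit_logistic(_dm(20, x1=x1, x2=x2), y)
        f_small = fit_logistic(_dm(20, x1=x1), y)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(f_big, f_small, 1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=-2.0, max_value=2.0),
        b=st.floats(min_value=0.1, max_value=4.0),
        seed=st.integers(min_value=0, max_value=50),
    )
    def test_invariant_to_affine_genotype_recoding(self, a, b, seed):
        """LRT unchanged when a covariate is recoded x -> a + b*x."""
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=60).astype(float)
        z = rng.normal(size=60)
        y = (rng.random(60) < 0.4).astype(float)
        if y.min() == y.max() or np.unique(g).size < 2:
            return
        null = fit_logistic(_dm(60, z=z), y)
        alt1 = fit_logistic(_dm(60, z=z, g=g), y)
        alt2 = fit_logistic(_dm(60, z=z, g=a + b * g), y)
        s1 = likelihood_ratio_test(null, alt1, 1).statistic
        s2 = likelihood_ratio_test(null, alt2, 1).statistic
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_null_p_values_uniform(self):
        """Under a global null the 1-d.f. LRT p-values are uniform (KS)."""
        rng = np.random.default_rng(123)
        pvals = np.empty(2000)
        for i in range(2000):
            x = rng.normal(size=200)
            y = (rng.random(200) < 0.5).astype(float)
            null = fit_logistic(_dm(200), y)
            alt = fit_logistic(_dm(200, x=x), y)
            pvals[i] = likelihood_ratio_test(null, alt, 1).p_value
        assert kstest(pvals, "uniform").pvalue > 0.001


class TestWald:
    def test_zero_coefficient_gives_p_one(self):
        y = np.array([0, 1, 0, 1], dtype=float)
        fit = fit_logistic(_dm(4), y)
        res = wald_test(fit, "intercept")
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_published_effect_and_se_row12(self):
        """pi = 0.417, se = 0.170 gives Wald stat ~ 6.016, p ~ 0.0142."""
        stat = (0.417 / 0.170) ** 2
        assert stat == pytest.approx(6.016, abs=2e-3)
        assert chi2.sf(stat, 1) == pytest.approx(0.0142, abs=2e-4)

    def test_published_effect_and_se_row6(self):
        """pi = -0.971, se = 0.370: Wald p in the band around 1e-2."""
        stat = (-0.971 / 0.370) ** 2
        p = chi2.sf(stat, 1)
        assert p == pytest.approx(0.00868, abs=2e-4)
        assert 0.0086 <= p <= 0.0287

    def test_testresult_validation(self):
        with pytest.raises(ValueError):
            TestResult(statistic=-1.0, df=1, p_value=0.5)
        with pytest.raises(ValueError):
            TestResult(statistic=1.0, df=1, p_value=1.5)
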