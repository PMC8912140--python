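import math

import numpy as np
import pytest
import statsmodels.api as sm

import relkin as rk
from relkin.exceptions import DegenerateDesign, InsufficientData
from relkin.linear_fit import _ic_from_sse


def _points(x, y, name="zero_order"):
    x = np.asarray(x, dtype=float)
    return rk.LinearizedPoints(
        model_name=name,
        x=x,
        y=np.asarray(y, dtype=float),
        included_index=np.arange(len(y)),
    )


class TestWithIntercept:
    def test_exact_line(self):
        fit = rk.fit_ols(_points([0, 1, 2], [0, 2, 4]))
        assert fit.coefficients[1] == pytest.approx(2.0)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.sse == 0.0
        assert fit.perfect_fit

    def test_hand_computed_normal_equations(self, hand_points):
        fit = rk.fit_ols(hand_points)
        assert fit.coefficients[1] == pytest.approx(0.5)
        assert fit.coefficients[0] == pytest.approx(2.0 / 3.0)
        assert fit.r2 == pytest.approx(0.75)
        assert fit.ssr == pytest.approx(0.5)
        assert fit.sst == pytest.approx(2.0 / 3.0)
        assert fit.sse == pytest.approx(1.0 / 6.0)

    def test_gaussian_aic_on_hand_design(self, hand_points):
        fit = rk.fit_ols(hand_points)
        assert fit.aic == pytest.approx(5.84, abs=0.01)
        assert fit.bic == pytest.approx(3.14, abs=0.01)


class TestThroughOrigin:
    def test_exact_proportional_line(self):
        fit = rk.refit_zero_intercept(_points([1, 2, 3], [2, 4, 6]))
        assert fit.coefficients[0] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert not fit.intercept_included

    def test_closed_form_slope(self):
        # slope = sum(xy)/sum(x^2) = 7/5
        fit = rk.refit_zero_intercept(_points([1, 2], [1, 3]))
        assert fit.coefficients[0] == pytest.approx(1.4)

    def test_zero_response_degenerates_gracefully(self):
        fit = rk.refit_zero_intercept(_points([1, 2, 3], [0, 0, 0]))
        assert fit.coefficients[0] == pytest.approx(0.0)
        assert fit.sse == 0.0

    def test_uncentered_r2_matches_reference(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 10, 8)
        y = 2 * x + rng.normal(0, 1, 8)
        fit = rk.refit_zero_intercept(_points(x, y))
        ref = sm.OLS(y, x[:, None]).fit()
        assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-10)
        assert fit.r2_adj == pytest.approx(ref.rsquared_adj, rel=1e-10)


class TestErrors:
    def test_all_x_identical_is_degenerate(self):
        with pytest.raises(DegenerateDesign):
            rk.fit_ols(_points([2, 2, 2, 2], [1, 2, 3, 4]))

    def test_no_residual_degree_of_freedom(self):
        with pytest.raises(InsufficientData):
            rk.fit_ols(_points([1, 2], [1, 2]))


class TestInformationCriteria:
    def test_formula_evaluation(self):
        aic, bic = _ic_from_sse(3, 2, 1.0 / 6.0)
        assert aic == pytest.approx(5.84, abs=0.01)
        assert bic == pytest.approx(3.14, abs=0.01)

    def test_doubling_sse_raises_aic_by_n_log2(self):
        a1, _ = _ic_from_sse(9, 2, 0.5)
        a2, _ = _ic_from_sse(9, 2, 1.0)
        assert a2 - a1 == pytest.approx(9 * math.log(2))

    def test_extra_coefficient_costs_two(self):
        a1, _ = _ic_from_sse(9, 2, 0.5)
        a2, _ = _ic_from_sse(9, 3, 0.5)
        assert a2 - a1 == pytest.approx(2.0)

    def test_perfect_fit_sentinel(self):
        fit = rk.fit_ols(_points([0, 1, 2], [0, 2, 4]))
        aic, bic = rk.information_criteria(fit)
        assert aic == -math.inf and bic == -math.inf


def _random_design(rng):
    n = int(rng.integers(5, 16))
    p = int(rng.integers(1, 4))
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(size=n)
    with_int = bool(rng.integers(0, 2))
    return X, y, with_int


class TestOracleEquivalence:
    def test_matches_reference_implementation(self):
        """Every reported statistic agrees with statsmodels OLS to 1e-8."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            X, y, with_int = _random_design(rng)
            pts = _points(X if X.shape[1] > 1 else X[:, 0], y)
            fit = rk.fit_ols(pts, with_intercept=with_int)
            Xs = sm.add_constant(X) if with_int else X
            ref = sm.OLS(y, Xs).fit()
            k = Xs.shape[1]

            def close(a, b):
                np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-10)

            close(fit.coefficients, ref.params)
            close(fit.std_errors, ref.bse)
            close(fit.t_values, ref.tvalues)
            close(fit.p_values, ref.pvalues)
            close(fit.r2, ref.rsquared)
            close(fit.r2_adj, ref.rsquared_adj)
            close(fit.f_statistic, ref.fvalue)
            close(fit.f_pvalue, ref.f_pvalue)
            close(fit.aic, -2 * ref.llf + 2 * (k + 1))
            close(fit.bic, -2 * ref.llf + math.log(len(y)) * (k + 1))

    def test_irrelevant_regressor_never_decreases_r2(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(6, 15))
            x = rng.normal(size=n)
            y = 1.5 * x + rng.normal(size=n)
            base = rk.fit_ols(_points(x, y))
            X2 = np.column_stack([x, rng.normal(size=n)])
            bigger = rk.fit_ols(_points(X2, y))
            assert bigger.r2 >= base.r2 - 1e-12

    def test_f_equals_slope_t_for_single_predictor(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            x = rng.uniform(0, 10, 8)
            y = 0.5 * x + rng.normal(0, 2, 8)
            fit = rk.fit_ols(_points(x, y))
            assert fit.f_pvalue == pytest.approx(fit.p_values[1], rel=1e-10)
            assert fit.f_statistic == pytest.approx(fit.t_values[1] ** 2, rel=1e-10)


class TestResultInvariants:
    def test_sum_of_squares_identity_and_bounds(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            X, y, with_int = _random_design(rng)
            fit = rk.fit_ols(
                _points(X if X.shape[1] > 1 else X[:, 0], y), with_intercept=with_int
            )
            assert fit.sst == pytest.approx(fit.ssr + fit.sse, rel=1e-8)
            assert fit.r2_adj <= fit.r2 + 1e-12
            assert fit.df_resid == fit.n_obs - len(fit.coefficients)
            mask = fit.std_errors > 0
            np.testing.assert_allclose(
                fit.t_values[mask],
                fit.coefficients[mask] / fit.std_errors[mask],
                rtol=1e-12,
            )

    def test_flat_record_serialization(self, hand_points):
        rec = rk.fit_ols(hand_points).to_record()
        assert rec["model"] == "zero_order"
        assert "coef_k0" in rec and "p_Q0" in rec
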