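import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posdev.calibration import (
    chi2_sf_quadrature,
    loo_cooks_oracle,
    loo_studentized_oracle,
    pinv_oracle,
)
from posdev.errors import InsufficientDFError, NestingError, UnderdeterminedFitError
from posdev.regression import (
    cooks_distance,
    fit_ols,
    influence_diagnostics,
    likelihood_ratio_test,
    log_likelihood_gaussian,
    studentized_residuals,
)


def _fit(y, X):
    return fit_ols(np.asarray(y, float), np.asarray(X, float), list(range(len(y))))


def design(*cols):
    return np.column_stack([np.asarray(c, float) for c in cols])


class TestFitOLS:
    def test_perfect_fit(self):
        fit = _fit([1, 2, 3], design(np.ones(3), [1, 2, 3]))
        assert fit.coefficients == pytest.approx([0.0, 1.0], abs=1e-10)
        assert np.max(np.abs(fit.residuals)) < 1e-10
        assert fit.r_squared == pytest.approx(1.0)

    def test_intercept_only_mean_model(self):
        fit = _fit([2, 4, 6], np.ones((3, 1)))
        assert fit.coefficients == pytest.approx([4.0])
        assert fit.residuals == pytest.approx([-2.0, 0.0, 2.0])
        assert fit.r_squared == pytest.approx(0.0)

    def test_hand_normal_equations(self):
        # slope = S_xy / S_xx = 10/10, intercept = ybar - slope * xbar
        fit = _fit([1, 1, 2, 3, 5], design(np.ones(5), [0, 1, 2, 3, 4]))
        assert fit.coefficients == pytest.approx([0.4, 1.0])

    def test_underdetermined_raises(self):
        with pytest.raises(UnderdeterminedFitError):
            _fit([1.0, 2.0], design(np.ones(2), [1, 2]))

    def test_zero_variance_outcome_degenerate(self):
        fit = _fit([3.0, 3.0, 3.0, 3.0], design(np.ones(4), [1, 2, 3, 4]))
        assert fit.degenerate
        assert fit.r_squared == 0.0

    def test_rank_deficient_minimum_norm(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        X = design(np.ones(10), x, 2 * x)  # exact collinearity
        y = 1.0 + 3.0 * x + rng.standard_normal(10)
        fit = _fit(y, X)
        assert fit.p == 2  # effective rank, not column count
        oracle = pinv_oracle(y, X)
        assert fit.coefficients == pytest.approx(oracle["coefficients"], abs=1e-8)
        assert fit.hat_diag == pytest.approx(oracle["hat_diag"], abs=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        X = design(np.ones(40), *rng.standard_normal((4, 40)))
        y = X @ np.array([1.0, 0.5, -0.3, 0.2, 0.0]) + rng.standard_normal(40)
        fit = _fit(y, X)
        model = sm.OLS(y, X).fit()
        assert fit.coefficients == pytest.approx(model.params, abs=1e-10)
        assert fit.r_squared == pytest.approx(model.rsquared, abs=1e-10)
        assert fit.log_likelihood == pytest.approx(model.llf, abs=1e-8)
        infl = model.get_influence()
        assert fit.hat_diag == pytest.approx(infl.hat_matrix_diag, abs=1e-10)
        assert studentized_residuals(fit) == pytest.approx(
            infl.resid_studentized_external, abs=1e-8
        )
        assert cooks_distance(fit) == pytest.approx(infl.cooks_distance[0], abs=1e-8)
        assert fit.coef_standard_errors() == pytest.approx(model.bse, abs=1e-10)


class TestStudentizedResiduals:
    def test_zero_residuals_give_zero(self):
        fit = _fit([1, 2, 3, 4], design(np.ones(4), [1, 2, 3, 4]))
        assert studentized_residuals(fit) == pytest.approx(np.zeros(4), abs=1e-12)

    def test_matches_leave_one_out_refit(self):
        rng = np.random.default_rng(7)
        X = design(np.ones(50), *rng.standard_normal((5, 50)))
        y = X @ rng.standard_normal(6) + rng.standard_normal(50)
        fit = _fit(y, X)
        assert np.max(np.abs(studentized_residuals(fit) - loo_studentized_oracle(y, X))) < 1e-8

    def test_outlier_sign_and_magnitude(self):
        X = design(np.ones(5), [1, 2, 3, 4, 5])
        y = np.array([2.0, 1.0, 4.0, 3.0, 10.0])
        fit = _fit(y, X)
        t = studentized_residuals(fit)
        assert np.argmax(np.abs(t)) == 4  # the y = 10 unit dominates
        nonzero = np.abs(fit.residuals) > 1e-8  # one residual is analytically 0
        assert np.all(np.sign(t[nonzero]) == np.sign(fit.residuals[nonzero]))

    def test_insufficient_df_raises(self):
        fit = _fit([1.0, 2.5, 3.0], design(np.ones(3), [1, 2, 3]))
        with pytest.raises(InsufficientDFError):
            studentized_residuals(fit)


class TestLogLikelihood:
    def test_closed_form_example(self):
        # n = 2, residuals (1, -1): RSS = 2 -> -(ln 2pi + ln 1 + 1) ~= -2.8379
        from posdev.regression import log_likelihood_from_rss

        assert log_likelihood_from_rss(2.0, 2) == pytest.approx(
            -(np.log(2 * np.pi) + 1.0), abs=1e-12
        )
        assert log_likelihood_from_rss(2.0, 2) == pytest.approx(-2.8379, abs=1e-4)

    def test_scale_property(self):
        rng = np.random.default_rng(1)
        X = design(np.ones(20), rng.standard_normal(20))
        y = X @ [1.0, 2.0] + rng.standard_normal(20)
        c = 3.7
        ll1 = _fit(y, X).log_likelihood
        ll2 = _fit(c * y, X).log_likelihood
        assert ll2 - ll1 == pytest.approx(-20 * np.log(c), abs=1e-8)

    def test_lrt_statistic_identity(self):
        # 2(ll_full - ll_reduced) = n ln(RSS_reduced / RSS_full)
        rng = np.random.default_rng(2)
        X1 = design(np.ones(30), rng.standard_normal(30))
        X2 = np.column_stack([X1, rng.standard_normal((30, 2))])
        y = X1 @ [1.0, 0.5] + rng.standard_normal(30)
        f1, f2 = _fit(y, X1), _fit(y, X2)
        stat = 2 * (f2.log_likelihood - f1.log_likelihood)
        assert stat == pytest.approx(30 * np.log(f1.rss / f2.rss), abs=1e-8)


class TestLikelihoodRatioTest:
    def _nested_pair(self, seed=3, n=40, extra=3):
        rng = np.random.default_rng(seed)
        X1 = design(np.ones(n), *rng.standard_normal((2, n)))
        X2 = np.column_stack([X1, rng.standard_normal((n, extra))])
        y = X1 @ [1.0, 0.5, -0.5] + rng.standard_normal(n)
        return _fit(y, X1), _fit(y, X2)

    def test_identical_models_df_zero(self):
        f1, _ = self._nested_pair()
        res = likelihood_ratio_test(f1, f1)
        assert (res.statistic, res.df, res.p_value) == (0.0, 0, 1.0)

    def test_duplicate_added_column_no_improvement(self):
        rng = np.random.default_rng(4)
        X1 = design(np.ones(20), rng.standard_normal(20))
        X2 = np.column_stack([X1, X1[:, 1]])  # adds no information
        y = X1 @ [1.0, 2.0] + rng.standard_normal(20)
        res = likelihood_ratio_test(_fit(y, X1), _fit(y, X2))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == 1.0  # df = rank difference = 0

    def test_p_value_matches_quadrature(self):
        f1, f2 = self._nested_pair()
        res = likelihood_ratio_test(f1, f2)
        assert res.df == 3
        assert res.p_value == pytest.approx(
            chi2_sf_quadrature(res.statistic, res.df), abs=1e-8
        )

    def test_statistic_nonnegative(self):
        for seed in range(10):
            f1, f2 = self._nested_pair(seed=seed)
            assert likelihood_ratio_test(f1, f2).statistic >= 0.0

    def test_mismatched_units_rejected(self):
        f1, f2 = self._nested_pair()
        f1.unit_ids = list(range(1, 41))
        with pytest.raises(NestingError):
            likelihood_ratio_test(f1, f2)

    def test_perfect_full_fit_degenerate(self):
        x = np.arange(5.0)
        X1 = design(np.ones(5))
        X2 = design(np.ones(5), x)
        y = 2.0 + 3.0 * x  # exact full fit, RSS = 0
        res = likelihood_ratio_test(_fit(y, X1), _fit(y, X2))
        assert res.p_value == 0.0 and res.degenerate


class TestInfluence:
    def test_balanced_design_never_flagged(self):
        # one-way balanced design: every h_ii = p/n exactly
        g = np.repeat([0, 1], 10)
        X = design(np.ones(20), g)
        rng = np.random.default_rng(5)
        y = 1.0 + g + rng.standard_normal(20)
        rep = influence_diagnostics(_fit(y, X))
        assert np.allclose(rep.hat_diag, 2 / 20)
        assert rep.flagged == []

    def test_extreme_covariate_has_high_leverage(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(20)
        x[0] = x[1:].mean() + 10 * x[1:].std()
        X = design(np.ones(20), x)
        y = x + rng.standard_normal(20)
        fit = _fit(y, X)
        assert np.argmax(fit.hat_diag) == 0
        assert fit.hat_diag[0] > 2 * fit.p / fit.n

    def test_cooks_distance_matches_refit_oracle(self):
        rng = np.random.default_rng(8)
        X = design(np.ones(30), *rng.standard_normal((4, 30)))
        y = X @ rng.standard_normal(5) + rng.standard_normal(30)
        fit = _fit(y, X)
        assert np.max(np.abs(cooks_distance(fit) - loo_cooks_oracle(y, X))) < 1e-8


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(8, 60),
    p_extra=st.integers(1, 5),
)
def test_fit_invariants_hold_on_random_problems(seed, n, p_extra):
    """With an intercept: residuals sum to ~0, leverages lie in [1/n, 1] and
    sum to p, R^2 in [0, 1], and the stored log-likelihood obeys its formula."""
    if n <= p_extra + 2:
        return
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p_extra))])
    y = X @ rng.standard_normal(p_extra + 1) + rng.standard_normal(n)
    fit = _fit(y, X)
    assert abs(fit.residuals.sum()) < 1e-8 * n * max(y.std(), 1.0)
    assert np.all(fit.hat_diag >= 1 / n - 1e-10) and np.all(fit.hat_diag <= 1 + 1e-10)
    assert fit.hat_diag.sum() == pytest.approx(fit.p, abs=1e-8)
    assert 0.0 <= fit.r_squared <= 1.0
    assert fit.log_likelihood == pytest.approx(
        -(n / 2) * (np.log(2 * np.pi) + np.log(fit.sigma2_mle) + 1.0), abs=1e-8
    )
    assert log_likelihood_gaussian(fit) == pytest.approx(fit.log_likelihood, abs=1e-10)
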