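import numpy as np
import pytest
from scipy import stats

from epicompress.models import (
    ConstantInputError,
    LinearFit,
    MarsFit,
    MarsTerm,
    bic_linear,
    fit_mars,
    fit_ols,
    kfold_cv,
    make_folds,
    pearson_with_pvalue,
    predict,
)


class TestFitOls:
    def test_exact_line(self):
        x = np.linspace(0, 1, 20)
        fit = fit_ols(x, 2 * x + 1)
        assert fit.coef[0] == pytest.approx(2, abs=1e-10)
        assert fit.intercept == pytest.approx(1, abs=1e-10)
        assert fit.rss == pytest.approx(0, abs=1e-16)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 5))
        y = rng.standard_normal(50)
        fit = fit_ols(X, y)
        A = np.hstack([np.ones((50, 1)), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coef], beta, atol=1e-8
        )

    def test_duplicated_column_warns_same_predictions(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(40)
        y = 3 * x + rng.standard_normal(40)
        single = fit_ols(x, y)
        with pytest.warns(UserWarning, match="rank-deficient"):
            dup = fit_ols(np.column_stack([x, x]), y)
        np.testing.assert_allclose(
            predict(dup, np.column_stack([x, x])), predict(single, x), atol=1e-8
        )

    def test_empty_error(self):
        with pytest.raises(ValueError):
            fit_ols(np.empty((0, 2)), np.empty(0))


class TestPredict:
    def test_linear(self):
        fit = LinearFit(intercept=1.0, coef=np.array([2.0]))
        assert predict(fit, np.array([[3.0]]))[0] == 7.0

    def test_mars_hinge(self):
        fit = MarsFit(intercept=0.0,
                      terms=[MarsTerm(0, +1, 0.5, 2.0)])
        out = predict(fit, np.array([[0.25], [1.0]]))
        assert list(out) == [0.0, 1.0]

    def test_column_mismatch_error(self):
        fit = LinearFit(intercept=0.0, coef=np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="columns"):
            predict(fit, np.ones((3, 3)))

    def test_training_predictions_reproduce_rss(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        fit = fit_ols(X, y)
        resid = y - predict(fit, X)
        assert resid @ resid == pytest.approx(fit.rss, rel=1e-10)


class TestFitMars:
    def test_noiseless_hinge_recovery(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.uniform(0, 1, 200))
        y = np.maximum(0.0, x - 0.5)
        fit = fit_mars(x, y, max_terms=10)
        knots = sorted(t.knot for t in fit.terms)
        gap = np.max(np.diff(x))
        assert min(abs(k - 0.5) for k in knots) <= gap
        x_new = rng.uniform(0, 1, 500)
        r, _ = pearson_with_pvalue(np.maximum(0, x_new - 0.5),
                                   predict(fit, x_new))
        assert r > 0.999

    def test_linear_signal_matches_ols(self):
        """Hinges can represent a line: MARS CV r within 0.02 of OLS CV r."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((400, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + 0.3 * rng.standard_normal(400)
        r_ols = kfold_cv(X, y, model="ols", seed=1).pearson_r
        r_mars = kfold_cv(X, y, model="mars", seed=1).pearson_r
        assert r_mars >= r_ols - 0.02

    def test_intercept_only_gcv_closed_form(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        fit = fit_mars(np.ones((5, 1)), y, max_terms=5)
        assert not fit.terms
        n = 5
        rss = float(np.sum((y - y.mean()) ** 2))
        assert fit.gcv == pytest.approx((rss / n) / (1 - 1 / n) ** 2)

    def test_tiny_sample_returns_intercept_only(self):
        fit = fit_mars(np.array([[1.0], [2.0]]), np.array([1.0, 3.0]))
        assert fit.terms == [] and fit.intercept == pytest.approx(2.0)


class TestKfoldCv:
    def test_noiseless_linear_r_is_one(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 2))
        y = X @ np.array([1.0, 2.0]) + 0.5
        res = kfold_cv(X, y, seed=3)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_null_world_r_small(self):
        """Without signal, CV r stays near zero (slight negative CV bias)."""
        rng = np.random.default_rng(9)
        rs = []
        for s in range(20):
            X = rng.standard_normal((2000, 5))
            y = rng.standard_normal(2000)
            rs.append(kfold_cv(X, y, seed=s).pearson_r)
        assert np.median(np.abs(rs)) < 0.08
        assert abs(np.mean(rs)) < 0.05
        assert np.max(np.abs(rs)) < 0.15

    def test_planted_signal_recovers_theoretical_r(self):
        """y = Xa + ε with var(signal)/var(total) = r*² gives CV r ≈ r*."""
        rng = np.random.default_rng(10)
        X = rng.standard_normal((2000, 5))
        a = np.array([1.0, 0.5, -0.5, 0.2, 0.0])
        signal = X @ a
        target = 0.9
        noise_sd = signal.std() * np.sqrt(1 / target**2 - 1)
        y = signal + noise_sd * rng.standard_normal(2000)
        res = kfold_cv(X, y, seed=11)
        assert res.pearson_r == pytest.approx(target, abs=0.03)

    def test_every_gene_predicted_once_and_deterministic(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((57, 3))
        y = rng.standard_normal(57)
        r1 = kfold_cv(X, y, k=10, seed=5)
        r2 = kfold_cv(X, y, k=10, seed=5)
        np.testing.assert_array_equal(r1.fold_assignment, r2.fold_assignment)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)
        assert len(np.unique(r1.fold_assignment)) == 10

    def test_k_larger_than_n_errors(self):
        with pytest.raises(ValueError):
            make_folds(5, 10, 0)


class TestPearson:
    def test_identity_and_anticorrelation(self):
        x = np.arange(10.0)
        r, p = pearson_with_pvalue(x, x)
        assert r == 1.0 and p == 0.0
        r, _ = pearson_with_pvalue(x, -x)
        assert r == -1.0

    def test_closed_form_t(self):
        """r = 0.5 at n = 102 gives t = 5.7735 and the Student-t p-value."""
        rng = np.random.default_rng(13)
        # construct vectors with exact sample correlation 0.5
        x = rng.standard_normal(102)
        z = rng.standard_normal(102)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)
        z /= z.std()
        y = 0.5 * x + np.sqrt(1 - 0.25) * z
        r, p = pearson_with_pvalue(x, y)
        assert r == pytest.approx(0.5, abs=1e-12)
        t = 0.5 * np.sqrt(100 / 0.75)
        assert t == pytest.approx(5.7735, abs=1e-4)
        assert p == pytest.approx(2 * stats.t.sf(t, 100), rel=1e-12)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            n = int(rng.integers(5, 200))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            r, p = pearson_with_pvalue(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_vector_distinct_error(self):
        with pytest.raises(ConstantInputError):
            pearson_with_pvalue(np.ones(10), np.arange(10.0))


class TestBic:
    def test_hand_formula(self):
        fit = LinearFit(intercept=0, coef=np.zeros(3), n_obs=100, rss=50.0)
        assert bic_linear(fit) == pytest.approx(
            100 * np.log(0.5) + 5 * np.log(100)
        )

    def test_useless_predictor_increases_bic(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(200)
        y = x + 0.5 * rng.standard_normal(200)
        junk = rng.standard_normal(200)
        small = fit_ols(x, y)
        big = fit_ols(np.column_stack([x, junk]), y)
        assert bic_linear(big) > bic_linear(small)

    def test_zero_rss_sentinel(self):
        fit = LinearFit(intercept=0, coef=np.zeros(1), n_obs=10, rss=0.0)
        with pytest.warns(UserWarning):
            assert bic_linear(fit) == -np.inf
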