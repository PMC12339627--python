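"""Penalized regression: objective, solver optimality, path, CV, prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundusquant.exceptions import DegenerateInputError, SchemaError, ValidationError
from fundusquant.lasso import (
    LassoConfig,
    LassoRegression,
    LassoResults,
    _cd_solve,
    _gram,
    fit_lasso,
    kkt_violation,
    lambda_grid,
    lasso_objective,
    loo_predictions,
    predict,
    soft_threshold,
    standardize,
)
from fundusquant.synthetic import generate_sparse_linear


@pytest.fixture
def small_problem(rng):
    X = rng.standard_normal((50, 5))
    beta = np.array([1.0, -2.0, 0.0, 3.0, 0.5])
    y = X @ beta + rng.standard_normal(50)
    return X, y


class TestStandardize:
    def test_columns_zero_mean_unit_sd(self, small_problem):
        dm = standardize(*small_problem)
        assert np.abs(dm.Xs.mean(axis=0)).max() < 1e-10
        assert np.abs(dm.Xs.std(axis=0) - 1).max() < 1e-10
        assert abs(dm.yc.mean()) < 1e-10

    def test_back_transform_roundtrip(self, small_problem):
        X, y = small_problem
        dm = standardize(X, y)
        np.testing.assert_allclose(dm.Xs * dm.x_sd + dm.x_mean, X, atol=1e-12)
        np.testing.assert_allclose(dm.yc + dm.y_mean, y, atol=1e-12)

    def test_constant_column_named(self, small_problem):
        X, y = small_problem
        X = X.copy()
        X[:, 2] = 7.0
        with pytest.raises(DegenerateInputError, match="ovality_ratio"):
            standardize(X, y, ["a", "b", "ovality_ratio", "d", "e"])


class TestObjective:
    def test_null_coefficients(self, small_problem):
        dm = standardize(*small_problem)
        expect = 0.5 * float(dm.yc @ dm.yc) / dm.n
        assert lasso_objective(0.0, np.zeros(5), dm, lam=0.3) == pytest.approx(expect)

    def test_lambda_zero_is_ols_loss(self, small_problem, rng):
        dm = standardize(*small_problem)
        beta = rng.standard_normal(5)
        resid = dm.yc - dm.Xs @ beta
        assert lasso_objective(0.0, beta, dm, lam=0.0) == pytest.approx(
            0.5 * float(resid @ resid) / dm.n, rel=1e-12
        )

    def test_term_by_term_oracle(self, small_problem, rng):
        dm = standardize(*small_problem)
        beta = rng.standard_normal(5)
        lam, alpha = 0.37, 0.4
        # independent direct summation of the penalized objective
        total = 0.0
        for i in range(dm.n):
            total += (dm.yc[i] - float(dm.Xs[i] @ beta)) ** 2
        total /= 2 * dm.n
        for bj in beta:
            total += lam * ((1 - alpha) / 2 * bj ** 2 + alpha * abs(bj))
        assert lasso_objective(0.0, beta, dm, lam, alpha) == pytest.approx(total, rel=1e-12)

    def test_negative_lambda_rejected(self, small_problem):
        dm = standardize(*small_problem)
        with pytest.raises(ValidationError):
            lasso_objective(0.0, np.zeros(5), dm, lam=-0.1)


class TestSoftThreshold:
    @pytest.mark.parametrize("z, g, expect", [(3, 1, 2), (-3, 1, -2), (0.5, 1, 0.0)])
    def test_values(self, z, g, expect):
        assert soft_threshold(z, g) == expect

    @settings(derandomize=True, max_examples=100)
    @given(z=st.floats(-1e6, 1e6), g=st.floats(0, 1e6))
    def test_shrinkage_properties(self, z, g):
        out = soft_threshold(z, g)
        assert abs(out) <= abs(z)
        assert out * z >= 0  # never flips sign


class TestFitLasso:
    def test_null_model_at_lambda_max(self, small_problem):
        dm = standardize(*small_problem)
        grid = lambda_grid(dm)
        m = fit_lasso(dm, grid[0])
        assert np.count_nonzero(m.coef) == 0
        assert m.intercept == pytest.approx(small_problem[1].mean(), rel=1e-12)

    def test_single_predictor_closed_form(self, rng):
        x = rng.standard_normal(200)
        y = 0.7 * x + rng.standard_normal(200)
        dm = standardize(x[:, None], y)
        for lam in (0.0, 0.05, 0.2, 1.0):
            m = fit_lasso(dm, lam)
            closed = soft_threshold(float(dm.Xs[:, 0] @ dm.yc) / dm.n, lam)
            assert m.beta_std[0] == pytest.approx(closed, abs=1e-8)

    def test_lambda_zero_matches_normal_equations(self, small_problem):
        X, y = small_problem
        m = fit_lasso(standardize(X, y), 0.0)
        Xc = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        np.testing.assert_allclose(m.coef, ols[1:], atol=1e-6)
        assert m.intercept == pytest.approx(ols[0], abs=1e-6)

    def test_kkt_conditions_at_convergence(self, rng):
        X, y, _ = generate_sparse_linear(300, 20, 5, seed=3)
        dm = standardize(X, y)
        for lam in (0.01, 0.05, 0.2):
            m = fit_lasso(dm, lam)
            assert kkt_violation(m, dm) < 1e-6

    def test_objective_non_increasing_across_sweeps(self, small_problem):
        dm = standardize(*small_problem)
        G, c = _gram(dm)
        beta = np.zeros(dm.p)
        lam = 0.05
        prev = lasso_objective(0.0, beta, dm, lam)
        for _ in range(30):
            _cd_solve(G, c, lam, 0.0, beta, 1, 0.0)  # exactly one sweep
            cur = lasso_objective(0.0, beta, dm, lam)
            assert cur <= prev + 1e-12
            prev = cur

    def test_shrinkage_monotone_in_lambda(self, rng):
        X, y, _ = generate_sparse_linear(200, 10, 4, seed=4)
        model = LassoRegression(y, X)
        path = model.fit_path()
        l1_norms = path.drop(columns="lambda").abs().sum(axis=1).to_numpy()
        # grid is descending, so the l1 norm must be non-decreasing
        assert np.all(np.diff(l1_norms) >= -1e-8)

    def test_two_predictor_exhaustive_grid_oracle(self, rng):
        X = rng.standard_normal((60, 2))
        X[:, 1] = 0.6 * X[:, 0] + 0.8 * X[:, 1]  # correlated pair
        y = 0.5 * X[:, 0] - 0.3 * X[:, 1] + 0.2 * rng.standard_normal(60)
        dm = standardize(X, y)
        lam = 0.07
        m = fit_lasso(dm, lam)
        G, c = _gram(dm)
        q = float(dm.yc @ dm.yc) / dm.n
        b = np.arange(-1.2, 1.2 + 1e-12, 1e-3)
        best, best_pair = np.inf, None
        for b1 in b:  # chunk over b1 to bound memory
            f = (
                0.5 * q - c[0] * b1 - c[1] * b
                + 0.5 * (G[0, 0] * b1 ** 2 + 2 * G[0, 1] * b1 * b + G[1, 1] * b ** 2)
                + lam * (abs(b1) + np.abs(b))
            )
            j = int(np.argmin(f))
            if f[j] < best:
                best, best_pair = f[j], (b1, b[j])
        np.testing.assert_allclose(m.beta_std, best_pair, atol=2e-3)

    def test_matches_sklearn_oracle(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y, _ = generate_sparse_linear(250, 15, 5, seed=8)
        dm = standardize(X, y)
        for lam in (0.02, 0.1):
            m = fit_lasso(dm, lam)
            sk = sklearn.Lasso(alpha=lam, tol=1e-12, max_iter=200000).fit(dm.Xs, dm.yc)
            np.testing.assert_allclose(m.beta_std, sk.coef_, atol=1e-7)


class TestLambdaGrid:
    def test_grid_shape_and_spacing(self, small_problem):
        dm = standardize(*small_problem)
        grid = lambda_grid(dm)
        assert len(grid) == 100
        ratios = grid[1:] / grid[:-1]
        assert np.ptp(ratios) < 1e-12
        assert grid[-1] == pytest.approx(1e-4 * grid[0], rel=1e-10)


class TestPredict:
    def test_null_model_predicts_mean(self, small_problem):
        X, y = small_problem
        dm = standardize(X, y)
        m = fit_lasso(dm, lambda_grid(dm)[0])
        assert predict(m, X[0]) == pytest.approx(y.mean())

    def test_refit_free_in_sample_consistency(self, small_problem):
        X, y = small_problem
        dm = standardize(X, y)
        m = fit_lasso(dm, 0.05)
        direct = dm.y_mean + dm.Xs @ m.beta_std
        np.testing.assert_allclose(predict(m, X), direct, atol=1e-10)

    def test_name_based_matching(self, small_problem):
        X, y = small_problem
        names = ["a", "b", "c", "d", "e"]
        m = fit_lasso(standardize(X, y, names), 0.05)
        row = pd.Series(X[3], index=names)
        shuffled = row[["d", "a", "e", "b", "c"]]
        assert predict(m, shuffled) == pytest.approx(predict(m, row), rel=1e-14)
        with pytest.raises(SchemaError, match="missing"):
            predict(m, row.drop("c"))

    def test_json_roundtrip_bit_exact(self, tmp_path, small_problem):
        X, y = small_problem
        model = LassoRegression(y, X)
        res = model.fit(0.03)
        path = tmp_path / "model.json"
        res.save(path)
        back = LassoResults.load(path)
        np.testing.assert_array_equal(back.predict(X), res.predict(X))


class TestLooPredictions:
    def test_too_few_rows(self, rng):
        with pytest.raises(ValidationError):
            loo_predictions(rng.standard_normal((5, 3)), rng.standard_normal(5))

    def test_deterministic_given_seed(self):
        X, y, _ = generate_sparse_linear(40, 6, 2, seed=12)
        a = loo_predictions(X, y, LassoConfig(seed=7))
        b = loo_predictions(X, y, LassoConfig(seed=7))
        np.testing.assert_array_equal(a.loo_predictions, b.loo_predictions)
        assert a.chosen_lambda == b.chosen_lambda

    def test_noiseless_sparse_signal_recovered(self):
        X, y, _ = generate_sparse_linear(120, 20, 4, noise_sd=0.0, seed=13)
        res = loo_predictions(X, y, LassoConfig(seed=0))
        r = np.corrcoef(y, res.loo_predictions)[0, 1]
        assert r > 0.95

    def test_single_lambda_mode_uses_full_data_penalty(self):
        X, y, _ = generate_sparse_linear(40, 6, 2, seed=12)
        res = loo_predictions(X, y, LassoConfig(seed=7, single_lambda=True))
        assert np.all(res.per_row_lambda == res.chosen_lambda)

    def test_prediction_i_independent_of_row_i(self):
        # perturbing only row i's response must not change prediction i
        # (its fold trains, and selects its penalty, on the other rows only)
        X, y, _ = generate_sparse_linear(30, 4, 2, seed=20)
        cfg = LassoConfig(seed=3)
        base = loo_predictions(X, y, cfg)
        y2 = y.copy()
        y2[5] += 100.0
        pert = loo_predictions(X, y2, cfg)
        assert pert.loo_predictions[5] == base.loo_predictions[5]
        assert pert.per_row_lambda[5] == base.per_row_lambda[5]


class TestModelResultsApi:
    def test_from_feature_table_and_summary(self, small_cohort):
        model = LassoRegression.from_feature_table(small_cohort, "AL")
        res = model.fit_cv(seed=0)
        assert res.params.shape == (42,)
        text = res.summary()
        assert "lambda" in text and "N.S." in text or "coef" in text
        assert res.cv_curve is not None and np.all(np.isfinite(res.cv_curve))

    def test_missing_outcome_column(self, small_cohort):
        with pytest.raises(SchemaError):
            LassoRegression.from_feature_table(small_cohort.drop(columns="AL"), "AL")
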