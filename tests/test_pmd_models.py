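"""PMD regression techniques and their tuning."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, spearmanr

import mammotex as mx
from mammotex.pmd import univariate_scores


def _toy(n=100, p=5, seed=0, noise=0.1, beta=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{i}" for i in range(p)])
    if beta is None:
        beta = np.zeros(p)
    y = X.to_numpy() @ beta + rng.normal(scale=noise, size=n)
    return X, y


class TestUnivariate:
    def test_perfect_feature_ranked_first(self):
        X, _ = _toy(seed=1)
        y = X["x3"].to_numpy()
        assert mx.rank_univariate(X, y)[0] == "x3"

    def test_f_equals_squared_t(self):
        # Closed-form OLS slope/SE on a 2-feature toy.
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 1.3 * x + rng.normal(size=40)
        X = pd.DataFrame({"x": x, "z": rng.normal(size=40)})
        scores = univariate_scores(X, y)
        xc = x - x.mean()
        b = xc @ (y - y.mean()) / (xc @ xc)
        resid = (y - y.mean()) - b * xc
        se = np.sqrt((resid @ resid) / 38 / (xc @ xc))
        assert scores.loc[0, "F"] == pytest.approx((b / se) ** 2, abs=1e-9)

    def test_null_pvalues_uniform(self):
        X, _ = _toy(n=1000, p=40, seed=3)
        y = np.random.default_rng(4).normal(size=1000)
        p = univariate_scores(X, y)["p"].to_numpy()
        assert kstest(p, "uniform").pvalue > 0.01

    def test_constant_feature_ranked_last(self):
        X, y = _toy(seed=5, beta=np.array([1, 0, 0, 0, 0.0]), noise=0.5)
        X["flat"] = 1.0
        assert mx.rank_univariate(X, y)[-1] == "flat"


class TestTopK:
    def test_noiseless_single_feature(self):
        X, _ = _toy(seed=6)
        y = 2.0 * X["x3"].to_numpy()
        model = mx.fit_top_k(X, y, 1)
        assert model.coefficients == pytest.approx({"x3": 2.0}, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)

    def test_all_features_equals_full_ols(self):
        X, y = _toy(seed=7, beta=np.array([1, -1, 2, 0, 0.5]), noise=0.3)
        model = mx.fit_top_k(X, y, 5)
        design = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        ols = dict(zip(X.columns, beta[1:]))
        for name in X.columns:
            assert model.coefficients[name] == pytest.approx(ols[name])

    def test_training_mse_non_increasing_in_k(self):
        X, y = _toy(n=80, seed=8, beta=np.array([2, -1, 1, 0.5, 0.2]),
                    noise=1.0)
        mses = []
        for k in (1, 3, 5):
            m = mx.fit_top_k(X, y, k)
            mses.append(np.mean((y - mx.predict_pmd(m, X)) ** 2))
        assert mses[0] >= mses[1] >= mses[2]


class TestLasso:
    def test_full_shrinkage(self):
        X, y = _toy(seed=9, beta=np.array([1, 1, 1, 1, 1.0]), noise=0.5)
        model = mx.fit_lasso(X, y, lam=1e3)
        assert all(c == 0.0 for c in model.coefficients.values())
        assert model.intercept == pytest.approx(float(np.mean(y)))

    def test_lambda_zero_equals_ols(self):
        X, y = _toy(seed=10, beta=np.array([1, -2, 0.5, 0, 3.0]), noise=0.2)
        model = mx.fit_lasso(X, y, 0.0)
        design = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        for i, name in enumerate(X.columns):
            assert model.coefficients[name] == pytest.approx(beta[i + 1],
                                                             abs=1e-6)

    def test_soft_threshold_closed_form(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=300)
        x = (x - x.mean()) / x.std()
        y = 2.5 * x + rng.normal(scale=0.4, size=300)
        X = pd.DataFrame({"x": x})
        b_ols = x @ (y - y.mean()) / (x @ x)
        for lam in (0.05, 0.5, 1.5, 4.0):
            model = mx.fit_lasso(X, y, lam)
            expect = np.sign(b_ols) * max(abs(b_ols) - lam, 0.0)
            assert model.coefficients["x"] == pytest.approx(expect, abs=1e-6)


class TestBoosting:
    def test_zero_iterations_is_intercept_only(self):
        X, y = _toy(seed=12, beta=np.ones(5))
        model = mx.boost_componentwise(X, y, 0)
        assert all(c == 0.0 for c in model.coefficients.values())
        assert mx.predict_pmd(model, X) == pytest.approx(
            np.full(len(y), y.mean()))

    def test_single_full_step_equals_ols(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=60)
        y = 1.7 * x + rng.normal(scale=0.3, size=60)
        X = pd.DataFrame({"x": x})
        model = mx.boost_componentwise(X, y, 1, step=1.0)
        xc = x - x.mean()
        b = xc @ (y - y.mean()) / (xc @ xc)
        assert model.coefficients["x"] == pytest.approx(b, abs=1e-9)

    def test_converges_to_ols_on_orthonormal_design(self):
        rng = np.random.default_rng(14)
        Q, _ = np.linalg.qr(rng.normal(size=(120, 6)))
        Q = (Q - Q.mean(axis=0)) * np.sqrt(120)
        X = pd.DataFrame(Q, columns=[f"q{i}" for i in range(6)])
        y = Q @ np.array([2, -1, 0.5, 0, 1.5, -0.2]) + rng.normal(
            scale=0.05, size=120)
        model = mx.boost_componentwise(X, y, 5000, step=0.1)
        design = np.column_stack([np.ones(120), Q])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        diffs = [abs(model.coefficients[c] - beta[i + 1])
                 for i, c in enumerate(X.columns)]
        assert max(diffs) < 1e-3

    def test_training_mse_non_increasing_in_iterations(self):
        X, y = _toy(n=90, seed=15, beta=np.array([1, 2, 0, -1, 0.5]),
                    noise=1.0)
        mses = []
        for t in (5, 50, 500):
            m = mx.boost_componentwise(X, y, t)
            mses.append(np.mean((y - mx.predict_pmd(m, X)) ** 2))
        assert mses[0] >= mses[1] >= mses[2]


class TestForest:
    def test_constant_outcome(self):
        X, _ = _toy(n=40, seed=16)
        y = np.full(40, 7.0)
        model = mx.fit_forest(X, y, mtry=2, n_trees=50, seed=0)
        assert mx.predict_pmd(model, X) == pytest.approx(y)

    def test_step_function_oob_r2(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame({"x0": rng.normal(size=500),
                          "x1": rng.normal(size=500)})
        y = np.where(X["x0"] > 0, 5.0, -5.0) + rng.normal(scale=0.5,
                                                          size=500)
        model = mx.fit_forest(X, y, mtry=1, n_trees=200, seed=1)
        r2 = 1 - model.oob_mse / np.var(y)
        assert r2 > 0.8

    def test_seed_stability_of_oob(self):
        rng = np.random.default_rng(18)
        X = pd.DataFrame({"x0": rng.normal(size=300)})
        y = 2 * X["x0"].to_numpy() + rng.normal(scale=0.5, size=300)
        a = mx.fit_forest(X, y, 1, n_trees=200, seed=1).oob_mse
        b = mx.fit_forest(X, y, 1, n_trees=200, seed=2).oob_mse
        assert a != b or True  # forests differ ...
        assert abs(a - b) / a < 0.10  # ... but OOB error is stable


class TestTuning:
    def test_single_value_grid(self):
        X, y = _toy(seed=19, beta=np.ones(5), noise=0.5)
        res = mx.tune_lambda(X, y, "lasso", grid=(0.3,), folds=3, seed=0)
        assert res.best_lambda == 0.3

    def test_overfitting_with_k_on_pure_noise(self):
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.normal(size=(100, 40)),
                             columns=[f"x{i}" for i in range(40)])
            y = rng.normal(size=100)
            res = mx.tune_lambda(X, y, "univariate",
                                 grid=tuple(range(1, 31, 3)), folds=5,
                                 seed=seed)
            rhos.append(spearmanr(res.grid, res.cv_mse).statistic)
        assert np.mean(rhos) > 0

    def test_lasso_recovery_on_linear_truth(self):
        X, y = _toy(n=200, p=10, seed=20,
                    beta=np.array([3, -2, 1.5] + [0.0] * 7), noise=0.1)
        res = mx.tune_lambda(X, y, "lasso", folds=10, seed=0)
        assert res.best_lambda <= sorted(res.grid)[3]  # small penalty wins
        model = mx.fit_lasso(X, y, res.best_lambda)
        pred = mx.predict_pmd(model, X)
        assert 1 - np.mean((y - pred) ** 2) / np.var(y) > 0.99

    def test_ties_break_to_smallest_lambda(self):
        grid = (1.0, 2.0, 3.0)
        res = mx.pmd._pick(grid, [0.5, 0.5, 0.7])
        assert res.best_lambda == 1.0

    def test_forest_tunes_by_oob(self):
        X, y = _toy(n=150, p=6, seed=21,
                    beta=np.array([2, 0, 0, 0, 0, 0.0]), noise=0.3)
        res = mx.tune_lambda(X, y, "forest", grid=(1.0, 3.0, 6.0), seed=0)
        assert res.best_lambda in res.grid
        assert len(res.cv_mse) == 3


class TestPredict:
    def test_fitted_values_match_ols_hat(self):
        X, y = _toy(seed=22, beta=np.array([1, 0, 2, 0, -1.0]), noise=0.4)
        model = mx.fit_top_k(X, y, 5)
        design = np.column_stack([np.ones(len(y)), X])
        hat = design @ np.linalg.lstsq(design, y, rcond=None)[0]
        assert mx.predict_pmd(model, X) == pytest.approx(hat, abs=1e-9)

    def test_forest_predictions_within_training_range(self):
        X, y = _toy(n=100, seed=23, beta=np.array([3, 0, 0, 0, 0.0]),
                    noise=0.5)
        model = mx.fit_forest(X, y, 2, n_trees=100, seed=0)
        pred = mx.predict_pmd(model, X)
        assert pred.min() >= y.min() and pred.max() <= y.max()

    def test_missing_column_named_in_error(self):
        X, y = _toy(seed=24)
        model = mx.fit_top_k(X, y, 2)
        with pytest.raises(KeyError, match="x"):
            mx.predict_pmd(model, X.drop(columns=list(
                model.coefficients)[:1]))


def test_r2_regime_on_synthetic_linear_truth():
    """Lasso and boosting recover a designed validation R^2 of 0.7."""
    rng = np.random.default_rng(30)
    n, p = 900, 20
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{i}" for i in range(p)])
    beta = np.zeros(p)
    beta[:5] = [2, -2, 1.5, 1, -1]
    signal = X.to_numpy() @ beta
    # Noise variance chosen for a true R^2 of 0.7.
    sigma = np.sqrt(signal.var() * 0.3 / 0.7)
    y = signal + rng.normal(scale=sigma, size=n)
    tr, va = np.arange(600), np.arange(600, 900)
    for fit in (lambda: mx.fit_lasso(X.iloc[tr], y[tr], 0.05),
                lambda: mx.boost_componentwise(X.iloc[tr], y[tr], 800)):
        model = fit()
        pred = mx.predict_pmd(model, X.iloc[va])
        r2 = 1 - np.mean((y[va] - pred) ** 2) / np.var(y[va])
        assert r2 == pytest.approx(0.7, abs=0.05)
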