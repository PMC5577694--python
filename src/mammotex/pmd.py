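"""Predicting percentage mammographic density (PMD) from texture features.

Four selection/regression techniques, each indexed by a tuning parameter
lambda:

* **univariate selection** — features ranked by the F test of their simple
  linear regression on PMD; lambda = number of top-ranked features entering
  an ordinary least-squares model (1..150);
* **lasso** — L1-penalized least squares, objective
  ``(1/2n)*RSS + lambda*sum|beta|``; lambda = penalty;
* **component-wise gradient boosting** (L2Boost with simple linear base
  learners) — starts from the empty model and in each iteration moves the
  single best-reducing coefficient by a small step (default 0.1);
  lambda = number of iterations;
* **random forest** — regression forest of 500 trees; lambda = number of
  candidate features per split (mtry).

Lambda is chosen by 10-fold cross-validation of the mean squared error on
the training data (out-of-bag error for the forest), smallest lambda on
ties. Features are standardized to unit variance inside lasso and
boosting; reported coefficients are on the original scale. Predictions are
not clipped to [0, 100]: the masking model consumes them linearly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "PMDModel", "TuningResult", "rank_univariate", "fit_top_k", "fit_lasso",
    "boost_componentwise", "fit_forest", "tune_lambda", "predict_pmd",
    "fit_pmd_model", "METHODS", "default_grid",
]

METHODS = ("univariate", "lasso", "boosting", "forest")


@dataclass
class PMDModel:
    """A fitted PMD predictor (linear coefficient map or forest)."""

    method: str
    lam: float
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    forest: RandomForestRegressor | None = None
    feature_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class TuningResult:
    """Cross-validated MSE per candidate lambda; smallest lambda on ties."""

    grid: tuple[float, ...]
    cv_mse: tuple[float, ...]
    best_lambda: float

    def __post_init__(self) -> None:
        best = min(self.cv_mse)
        winners = [g for g, m in zip(self.grid, self.cv_mse) if m == best]
        if self.best_lambda != min(winners):
            raise ValueError("best_lambda does not attain the minimal MSE")


def _matrix(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = [c for c in X.columns if c != "patient_id"]
    return X[names].to_numpy(dtype=float), names


def _standardize(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = A.mean(axis=0)
    scale = A.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (A - mean) / scale, mean, scale


# ---------------------------------------------------------------------------
# Univariate selection
# ---------------------------------------------------------------------------

def univariate_scores(X: pd.DataFrame, y: np.ndarray
                      ) -> pd.DataFrame:
    """Per-feature F statistic and p-value of the simple regression on y.

    F equals the squared t statistic of the slope. Constant features get
    F = 0, p = 1 and are ranked last.
    """
    A, names = _matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = A - A.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    syy = float((yc ** 2).sum())
    sxy = xc.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((sxx > 0) & (syy > 0), sxy ** 2 / (sxx * syy), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        F = np.where(r2 < 1.0, (n - 2) * r2 / (1.0 - r2), np.inf)
    p = stats.f.sf(F, 1, n - 2)
    p = np.where(sxx > 0, p, 1.0)
    return pd.DataFrame({"feature": names, "F": F, "p": p})


def rank_univariate(X: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Feature names ordered by increasing p-value (ties: input order)."""
    scores = univariate_scores(X, y)
    order = np.argsort(scores["p"].to_numpy(), kind="stable")
    return scores["feature"].to_numpy()[order].tolist()


def fit_top_k(X: pd.DataFrame, y: np.ndarray, k: int,
              ranking: list[str] | None = None) -> PMDModel:
    """OLS on the k top-ranked features."""
    A, names = _matrix(X)
    y = np.asarray(y, dtype=float)
    if not 1 <= k <= len(names):
        raise ValueError(f"k={k} outside [1, {len(names)}]")
    if ranking is None:
        ranking = rank_univariate(X, y)
    selected = ranking[:k]
    sub = X[selected].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(y)), sub])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient design: collinear features absorbed "
                      "by least squares", stacklevel=2)
    return PMDModel(method="univariate", lam=float(k),
                    intercept=float(beta[0]),
                    coefficients=dict(zip(selected, beta[1:].tolist())))


# ---------------------------------------------------------------------------
# Lasso
# ---------------------------------------------------------------------------

def fit_lasso(X: pd.DataFrame, y: np.ndarray, lam: float) -> PMDModel:
    """L1-penalized least squares; coefficients on the original scale."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    A, names = _matrix(X)
    y = np.asarray(y, dtype=float)
    As, mean, scale = _standardize(A)
    if lam == 0.0:
        est = LinearRegression().fit(As, y)
    else:
        est = Lasso(alpha=lam, fit_intercept=True, max_iter=50_000,
                    tol=1e-8).fit(As, y)
    beta = np.asarray(est.coef_, dtype=float) / scale
    intercept = float(est.intercept_) - float((beta * mean).sum())
    return PMDModel(method="lasso", lam=float(lam), intercept=intercept,
                    coefficients=dict(zip(names, beta.tolist())))


def _lasso_max_lambda(X: pd.DataFrame, y: np.ndarray) -> float:
    A, _ = _matrix(X)
    y = np.asarray(y, dtype=float)
    As, _, _ = _standardize(A)
    return float(np.abs(As.T @ (y - y.mean())).max() / len(y))


# ---------------------------------------------------------------------------
# Component-wise gradient boosting (L2Boost)
# ---------------------------------------------------------------------------

def _boost_path(As: np.ndarray, y: np.ndarray, iters: tuple[int, ...],
                step: float) -> tuple[float, np.ndarray]:
    """Coefficient snapshots of L2Boost on standardized columns.

    Returns ``(intercept, snapshots)`` with one coefficient row per
    requested iteration count. Columns with zero norm never win a step.
    """
    n, p = As.shape
    norms = (As ** 2).sum(axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    intercept = float(np.mean(y))
    u = y - intercept
    beta = np.zeros(p)
    snapshots = np.zeros((len(iters), p))
    targets = {it: idx for idx, it in enumerate(iters)}
    max_iter = max(iters)
    if 0 in targets:
        snapshots[targets[0]] = beta
    for t in range(1, max_iter + 1):
        b = (As.T @ u) / safe
        # RSS reduction of base learner j is b_j^2 * ||x_j||^2.
        gain = b ** 2 * norms
        j = int(np.argmax(gain))
        if gain[j] <= 0:
            # All residual correlations vanished; remaining snapshots equal
            # the current coefficients.
            for it, idx in targets.items():
                if it >= t:
                    snapshots[idx] = beta
            break
        beta[j] += step * b[j]
        u -= step * b[j] * As[:, j]
        if t in targets:
            snapshots[targets[t]] = beta
    return intercept, snapshots


def boost_componentwise(X: pd.DataFrame, y: np.ndarray, n_iter: int,
                        step: float = 0.1) -> PMDModel:
    """L2Boost with simple linear base learners.

    Starts from the intercept-only model (the mean of y) and per iteration
    updates the coefficient of the single feature whose least-squares base
    learner most reduces the residual sum of squares, by ``step`` times its
    least-squares slope.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if not 0 < step <= 1:
        raise ValueError("step must lie in (0, 1]")
    A, names = _matrix(X)
    y = np.asarray(y, dtype=float)
    As, mean, scale = _standardize(A)
    intercept0, snaps = _boost_path(As, y, (n_iter,), step)
    beta = snaps[0] / scale
    intercept = intercept0 - float((beta * mean).sum())
    return PMDModel(method="boosting", lam=float(n_iter), intercept=intercept,
                    coefficients=dict(zip(names, beta.tolist())))


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------

def fit_forest(X: pd.DataFrame, y: np.ndarray, mtry: int,
               n_trees: int = 500, seed: int = 0) -> PMDModel:
    """Regression forest with bootstrap resampling and OOB error."""
    A, names = _matrix(X)
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    if not 1 <= mtry <= len(names):
        raise ValueError(f"mtry={mtry} outside [1, {len(names)}]")
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, bootstrap=True,
        oob_score=True, random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse OOB coverage on tiny n
        forest.fit(A, y)
    model = PMDModel(method="forest", lam=float(mtry), intercept=0.0,
                     forest=forest, feature_names=tuple(names))
    oob = forest.oob_prediction_
    model.oob_mse = float(np.mean((oob - y) ** 2))  # type: ignore[attr-defined]
    return model


def _mtry_grid(p: int) -> tuple[int, ...]:
    raw = {max(1, round(p / 10)), max(1, round(p / 5)),
           max(1, round(p / 3)), max(1, round(p / 2))}
    return tuple(sorted(raw))


# ---------------------------------------------------------------------------
# Tuning and prediction
# ---------------------------------------------------------------------------

def default_grid(method: str, X: pd.DataFrame,
                 y: np.ndarray) -> tuple[float, ...]:
    """Default lambda grid per method, sized to the data at hand."""
    p = len([c for c in X.columns if c != "patient_id"])
    n = len(X)
    if method == "univariate":
        kmax = min(150, p, n - 2)
        return tuple(float(k) for k in range(1, kmax + 1))
    if method == "lasso":
        lam_max = _lasso_max_lambda(X, y)
        return tuple(np.geomspace(lam_max, lam_max * 1e-3, 20).tolist())
    if method == "boosting":
        return tuple(float(t) for t in
                     (10, 25, 50, 100, 200, 400, 800, 1200, 2000))
    if method == "forest":
        return tuple(float(m) for m in _mtry_grid(p))
    raise ValueError(f"unknown method {method!r}")


def tune_lambda(X: pd.DataFrame, y: np.ndarray, method: str,
                grid: tuple[float, ...] | None = None, folds: int = 10,
                seed: int = 0, step: float = 0.1) -> TuningResult:
    """Pick lambda by K-fold CV of the MSE (OOB error for the forest).

    The fold assignment is fixed by ``seed`` and shared across the whole
    grid; the winner is the grid value with the smallest mean held-out MSE,
    the smallest such value on ties.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = default_grid(method, X, y)
    if len(grid) == 0:
        raise ValueError("empty tuning grid")
    grid = tuple(float(g) for g in grid)

    if method == "forest":
        mses = []
        for mtry in grid:
            model = fit_forest(X, y, int(mtry), seed=seed)
            mses.append(model.oob_mse)  # type: ignore[attr-defined]
        return _pick(grid, mses)

    if folds < 2:
        raise ValueError("folds must be >= 2")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    names = [c for c in X.columns if c != "patient_id"]
    Xf = X[names]
    errors = np.zeros((folds, len(grid)))
    for f, (tr, va) in enumerate(kf.split(Xf)):
        Xtr, Xva = Xf.iloc[tr], Xf.iloc[va]
        ytr, yva = y[tr], y[va]
        if method == "univariate":
            ranking = rank_univariate(Xtr, ytr)
            for gi, k in enumerate(grid):
                model = fit_top_k(Xtr, ytr, int(k), ranking=ranking)
                errors[f, gi] = float(np.mean(
                    (yva - predict_pmd(model, Xva)) ** 2))
        elif method == "lasso":
            for gi, lam in enumerate(grid):
                model = fit_lasso(Xtr, ytr, lam)
                errors[f, gi] = float(np.mean(
                    (yva - predict_pmd(model, Xva)) ** 2))
        else:  # boosting: one path fit serves the whole iteration grid
            A = Xtr.to_numpy(dtype=float)
            As, mean, scale = _standardize(A)
            iters = tuple(int(g) for g in grid)
            intercept0, snaps = _boost_path(As, ytr, iters, step)
            Ava = (Xva.to_numpy(dtype=float) - mean) / scale
            preds = intercept0 + Ava @ snaps.T
            errors[f] = ((yva[:, None] - preds) ** 2).mean(axis=0)
    return _pick(grid, errors.mean(axis=0).tolist())


def _pick(grid: tuple[float, ...], mses: list[float]) -> TuningResult:
    best = min(mses)
    winner = min(g for g, m in zip(grid, mses) if m == best)
    return TuningResult(grid=grid, cv_mse=tuple(float(m) for m in mses),
                        best_lambda=float(winner))


def fit_pmd_model(X: pd.DataFrame, y: np.ndarray, method: str,
                  grid: tuple[float, ...] | None = None, folds: int = 10,
                  seed: int = 0, step: float = 0.1) -> PMDModel:
    """Tune lambda, then fit the chosen technique on all of (X, y)."""
    tuning = tune_lambda(X, y, method, grid=grid, folds=folds, seed=seed,
                         step=step)
    lam = tuning.best_lambda
    if method == "univariate":
        model = fit_top_k(X, np.asarray(y, float), int(lam))
    elif method == "lasso":
        model = fit_lasso(X, np.asarray(y, float), lam)
    elif method == "boosting":
        model = boost_componentwise(X, np.asarray(y, float), int(lam),
                                    step=step)
    else:
        model = fit_forest(X, np.asarray(y, float), int(lam), seed=seed)
    model.tuning = tuning  # type: ignore[attr-defined]
    return model


def predict_pmd(model: PMDModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted PMD values (not clipped to [0, 100])."""
    if model.forest is not None:
        missing = [n for n in model.feature_names if n not in X.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        return model.forest.predict(
            X[list(model.feature_names)].to_numpy(dtype=float))
    missing = [n for n in model.coefficients if n not in X.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    out = np.full(len(X), model.intercept, dtype=float)
    for name, coef in model.coefficients.items():
        if coef != 0.0:
            out += coef * X[name].to_numpy(dtype=float)
    return out
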