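"""Conditional-quantile estimators under one prediction contract.

Two families:

* :class:`LinearQuantileRegression` — linear quantile regression fit by
  check-loss (pinball) minimization, one coefficient vector per level.
* :class:`QuantileRegressionForest` — a random forest whose leaves retain
  every training response; conditional quantiles come from the
  leaf-co-occurrence-weighted empirical distribution of the training
  responses, averaged over trees (the Meinshausen construction).

Both expose ``fit(X, y)`` and ``predict_quantiles(X, alphas)``; quantile
crossing is removed by sorting the per-row predictions across levels.
"""

from __future__ import annotations

import pickle
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "LinearQuantileRegression",
    "QuantileRegressionForest",
    "fit_linear_quantile",
    "fit_quantile_forest",
    "leaf_cooccurrence_weights",
    "pinball_loss",
    "predict_quantiles",
    "weighted_quantile",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1


def pinball_loss(y: np.ndarray, pred: np.ndarray, alpha: float) -> float:
    """Mean check loss rho_alpha(y - pred), rho_alpha(u) = u(alpha - 1{u<0})."""
    u = np.asarray(y, float) - np.asarray(pred, float)
    return float(np.mean(u * (alpha - (u < 0))))


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    return X, y


def _check_alphas(alphas: Sequence[float]) -> np.ndarray:
    a = np.asarray(alphas, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("alphas must be non-empty")
    if np.any((a <= 0) | (a >= 1)):
        raise ValueError(f"quantile levels must lie in (0, 1), got {a}")
    if np.any(np.diff(a) < 0):
        raise ValueError("alphas must be sorted ascending")
    return a


class LinearQuantileRegression:
    """Linear conditional-quantile model, one check-loss fit per level.

    The training data are retained so quantiles at any level can be
    evaluated lazily; fits are cached per alpha.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept
        self._X = None
        self._y = None
        self._coefs: dict[float, np.ndarray] = {}
        self.feature_names_: list[str] | None = None
        self.n_obs_: int | None = None

    def fit(self, X, y, feature_names: Sequence[str] | None = None) -> "LinearQuantileRegression":
        X, y = _validate_xy(X, y)
        design = self._design(X)
        if X.shape[0] < design.shape[1] + 1:
            raise ValueError(
                f"need at least {design.shape[1] + 1} observations, got {X.shape[0]}"
            )
        names = list(feature_names) if feature_names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
        self._check_rank(design, names)
        self._X, self._y = X, y
        self._coefs = {}
        self.feature_names_ = names
        self.n_obs_ = X.shape[0]
        return self

    def _design(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(X.shape[0]), X]) if self.fit_intercept else X

    def _check_rank(self, design: np.ndarray, names: Sequence[str]) -> None:
        # flag near-zero pivots of the QR factorization as collinear columns
        r = np.abs(np.diag(np.linalg.qr(design, mode="r")))
        bad = np.nonzero(r < 1e-10 * max(r.max(), 1.0))[0]
        if bad.size:
            cols = ["intercept", *names] if self.fit_intercept else list(names)
            raise ValueError(
                "rank-deficient design; collinear columns: "
                + ", ".join(cols[j] for j in bad)
            )

    def coef(self, alpha: float) -> np.ndarray:
        """Coefficient vector (intercept first when fitted) at level alpha."""
        if self._X is None:
            raise RuntimeError("model is not fitted")
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        if alpha not in self._coefs:
            res = sm.QuantReg(self._y, self._design(self._X)).fit(
                q=alpha, max_iter=2000
            )
            self._coefs[alpha] = np.asarray(res.params, dtype=float)
        return self._coefs[alpha]

    def predict_quantiles(self, X, alphas: Sequence[float]) -> np.ndarray:
        if self._X is None:
            raise RuntimeError("model is not fitted")
        a = _check_alphas(alphas)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = self._design(X)
        out = np.column_stack([design @ self.coef(al) for al in a])
        return np.sort(out, axis=1)


def weighted_quantile(
    y: np.ndarray, weights: np.ndarray, alphas: Sequence[float]
) -> np.ndarray:
    """Type-1 (left-continuous inverse CDF) quantiles of a weighted sample.

    Returns the smallest y whose cumulative normalized weight reaches each
    alpha.  ``weights`` may be a matrix (one row per query point).
    """
    y = np.asarray(y, dtype=float).ravel()
    a = _check_alphas(alphas)
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    if w.shape[1] != y.size:
        raise ValueError("weights and y have incompatible shapes")
    order = np.argsort(y, kind="stable")
    ys = y[order]
    cw = np.cumsum(w[:, order], axis=1)
    cw /= cw[:, -1:]
    out = np.empty((w.shape[0], a.size))
    for i in range(w.shape[0]):
        idx = np.searchsorted(cw[i], a - 1e-12, side="left")
        out[i] = ys[np.minimum(idx, y.size - 1)]
    return out


def leaf_cooccurrence_weights(
    leaves_train: np.ndarray, leaves_query: np.ndarray
) -> np.ndarray:
    """Forest weights w(i, x): per tree, 1/|leaf| for training points sharing
    the query's leaf, averaged over trees.  Rows sum to 1.

    ``leaves_train`` is (n_train, n_trees), ``leaves_query`` (n_query, n_trees)
    — leaf indices as returned by ``RandomForestRegressor.apply``.
    """
    lt = np.atleast_2d(np.asarray(leaves_train))
    lq = np.atleast_2d(np.asarray(leaves_query))
    if lt.shape[1] != lq.shape[1]:
        raise ValueError("train and query leaf matrices disagree on tree count")
    n, T = lt.shape
    m = lq.shape[0]
    W = np.zeros((m, n))
    for t in range(T):
        col = lt[:, t]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        left = np.searchsorted(sorted_col, lq[:, t], side="left")
        right = np.searchsorted(sorted_col, lq[:, t], side="right")
        for j in range(m):
            if right[j] == left[j]:  # query leaf empty of training points
                continue
            W[j, order[left[j] : right[j]]] += 1.0 / (right[j] - left[j])
    return W / T


class QuantileRegressionForest:
    """Quantile regression forest: leaves retain all training responses.

    The forest structure comes from scikit-learn's
    :class:`~sklearn.ensemble.RandomForestRegressor`; prediction replaces the
    per-leaf mean with the full weighted empirical distribution of training
    responses (weights over all n training points, per the original
    construction), read off with the type-1 quantile convention.
    """

    def __init__(
        self,
        n_trees: int = 500,
        min_leaf: int = 5,
        max_features: int | float | None = None,
        seed: int = 0,
    ):
        if n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {n_trees}")
        if min_leaf < 1:
            raise ValueError(f"min_leaf must be >= 1, got {min_leaf}")
        self.n_trees = n_trees
        self.min_leaf = min_leaf
        self.max_features = max_features
        self.seed = seed
        self._forest: RandomForestRegressor | None = None
        self._leaves_train: np.ndarray | None = None
        self._y: np.ndarray | None = None
        self.n_obs_: int | None = None

    def fit(self, X, y, feature_names: Sequence[str] | None = None) -> "QuantileRegressionForest":
        X, y = _validate_xy(X, y)
        if self.min_leaf > X.shape[0]:
            raise ValueError(
                f"min_leaf ({self.min_leaf}) exceeds n_samples ({X.shape[0]})"
            )
        self._forest = RandomForestRegressor(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_leaf,
            max_features=self.max_features if self.max_features is not None else 1.0,
            random_state=self.seed,
            n_jobs=1,
        ).fit(X, y)
        self._leaves_train = self._forest.apply(X)
        self._y = y
        self.n_obs_ = X.shape[0]
        self.feature_names_ = list(feature_names) if feature_names is not None else None
        return self

    def weights(self, X) -> np.ndarray:
        """Meinshausen weights of every training point for each query row."""
        if self._forest is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return leaf_cooccurrence_weights(self._leaves_train, self._forest.apply(X))

    def predict_quantiles(self, X, alphas: Sequence[float]) -> np.ndarray:
        a = _check_alphas(alphas)
        W = self.weights(X)
        return np.sort(weighted_quantile(self._y, W, a), axis=1)


def fit_linear_quantile(X, y, alpha: float) -> LinearQuantileRegression:
    """Fit linear QR and eagerly solve the given level (cached)."""
    model = LinearQuantileRegression().fit(X, y)
    model.coef(alpha)
    return model


def fit_quantile_forest(
    X,
    y,
    n_trees: int = 500,
    min_leaf: int = 5,
    max_features: int | float | None = None,
    seed: int = 0,
) -> QuantileRegressionForest:
    return QuantileRegressionForest(
        n_trees=n_trees, min_leaf=min_leaf, max_features=max_features, seed=seed
    ).fit(X, y)


def predict_quantiles(model, X, alphas: Sequence[float]) -> np.ndarray:
    """Evaluate conditional quantiles; rows are non-decreasing across alphas."""
    return model.predict_quantiles(X, alphas)


def save_model(model, path) -> None:
    """Serialize a fitted model to a versioned binary artifact."""
    with open(path, "wb") as fh:
        pickle.dump({"format_version": _MODEL_FORMAT_VERSION, "model": model}, fh)


def load_model(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model artifact version: {payload.get('format_version')}")
    return payload["model"]
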