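"""Feature optimization: random-forest weights x Pearson significance.

A feature survives when (a) its normalized random-forest importance
weight strictly exceeds ``weight_threshold`` (default 0.03) and (b) its
Pearson correlation with measured LAI is extremely significant
(two-sided p <= ``p_threshold``, default 0.01).  The *magnitude* of the
correlation is deliberately not thresholded — only its significance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.utils.validation import check_is_fitted


class DegenerateTargetError(ValueError):
    """Raised when the regression target is constant."""


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.DataFrame(np.asarray(table))


def rf_importance_weights(
    table,
    y,
    seed: int = 0,
    n_trees: int = 1000,
    method: str = "permutation",
    n_repeats: int = 5,
) -> np.ndarray:
    """Normalized random-forest importance weight per feature.

    ``method="permutation"`` (default) scores each feature by the mean
    increase in out-of-sample error when that column is shuffled — more
    comparable across correlated features than impurity importance, which
    remains available via ``method="impurity"``.  Negative permutation
    scores are floored at zero; weights are normalized to sum to 1 so the
    selection threshold is scale-meaningful.
    """
    X = _as_frame(table)
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("importance weights need at least 2 features")
    if np.ptp(y) == 0:
        raise DegenerateTargetError("target LAI vector is constant")
    mtry = max(1, X.shape[1] // 3)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
    )
    forest.fit(X.to_numpy(), y)
    if method == "impurity":
        raw = forest.feature_importances_
    elif method == "permutation":
        result = permutation_importance(
            forest, X.to_numpy(), y, n_repeats=n_repeats, random_state=seed, n_jobs=1
        )
        raw = np.clip(result.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown importance method {method!r}")
    total = raw.sum()
    if total == 0:
        # no feature carries signal; spread uniformly so weights still sum to 1
        return np.full(X.shape[1], 1.0 / X.shape[1])
    return raw / total


def pearson_with_target(table, y) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p (t distribution, n-2 df) per feature.

    Constant features are reported as r = 0, p = 1 with a warning instead
    of raising, so one degenerate column cannot abort a selection run.
    """
    X = _as_frame(table)
    y = np.asarray(y, dtype=float)
    r = np.empty(X.shape[1])
    p = np.empty(X.shape[1])
    for k, col in enumerate(X.columns):
        x = X[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"feature {col!r} is constant; reporting r=0, p=1", stacklevel=2)
            r[k], p[k] = 0.0, 1.0
            continue
        res = stats.pearsonr(x, y)
        r[k], p[k] = res.statistic, res.pvalue
    return r, p


def select_features(
    result: pd.DataFrame, w_thresh: float = 0.03, p_thresh: float = 0.01
) -> list[str]:
    """Names passing weight > w_thresh (strict) AND p <= p_thresh.

    ``result`` is a frame with columns ``feature``, ``weight``, ``p``
    (as produced by :meth:`ImportanceCorrelationSelector.result_`).
    """
    keep = (result["weight"].to_numpy() > w_thresh) & (result["p"].to_numpy() <= p_thresh)
    return [str(f) for f in result["feature"].to_numpy()[keep]]


class ImportanceCorrelationSelector(TransformerMixin, BaseEstimator):
    """Select features by random-forest weight and Pearson significance.

    Parameters
    ----------
    weight_threshold : float, default 0.03
        Strict lower bound on the normalized importance weight.
    p_threshold : float, default 0.01
        Upper bound on the two-sided Pearson p-value ("extremely
        significant"; set 0.001 for the stricter convention).
    n_trees : int, default 1000
        Trees in the importance forest.
    importance : {"permutation", "impurity"}
    random_state : int, default 0

    Attributes
    ----------
    weights_ : ndarray of normalized importance weights (sums to 1)
    pearson_r_, p_values_ : ndarray per feature
    support_ : boolean mask of selected features
    selected_features_ : list of selected column names
    result_ : DataFrame (feature, weight, r, p, selected)
    """

    def __init__(
        self,
        weight_threshold: float = 0.03,
        p_threshold: float = 0.01,
        n_trees: int = 1000,
        importance: str = "permutation",
        n_repeats: int = 5,
        random_state: int = 0,
    ):
        self.weight_threshold = weight_threshold
        self.p_threshold = p_threshold
        self.n_trees = n_trees
        self.importance = importance
        self.n_repeats = n_repeats
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_frame(X)
        if X.isna().to_numpy().any():
            raise ValueError("feature table contains missing values; apply masking policy first")
        if X.shape[0] < 10:
            raise ValueError("feature selection needs at least 10 samples")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.weights_ = rf_importance_weights(
            X,
            y,
            seed=self.random_state,
            n_trees=self.n_trees,
            method=self.importance,
            n_repeats=self.n_repeats,
        )
        self.pearson_r_, self.p_values_ = pearson_with_target(X, y)
        self.support_ = (self.weights_ > self.weight_threshold) & (
            self.p_values_ <= self.p_threshold
        )
        self.selected_features_ = [str(f) for f in self.feature_names_in_[self.support_]]
        self.result_ = pd.DataFrame(
            {
                "feature": self.feature_names_in_,
                "weight": self.weights_,
                "r": self.pearson_r_,
                "p": self.p_values_,
                "selected": self.support_,
            }
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = _as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            # allow any order/superset as long as all fitted columns exist
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValueError(f"feature table is missing fitted columns: {missing}")
        return X[self.selected_features_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_.copy()
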