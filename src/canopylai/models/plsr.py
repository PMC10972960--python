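"""Partial least squares regression with CV-selected component count.

The number of latent components is the only tuned hyperparameter: it is
chosen to minimize K-fold cross-validated RMSE on the training set, with
ties broken toward the fewest components.  Predictors are standardized to
unit variance inside the PLS fit (NIPALS, via scikit-learn).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted


class DegenerateDesignError(ValueError):
    """Raised when the design matrix carries no usable variance."""


def _as_matrix(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


class PLSRegressorCV(RegressorMixin, BaseEstimator):
    """PLS regression whose component count is chosen by K-fold RMSE.

    Parameters
    ----------
    max_components : int or None
        Upper bound on the candidate component counts; capped at
        min(n_features, n_samples - 1) regardless.
    cv_folds : int, default 10
    scale : bool, default True
        Standardize predictors to unit variance (the package convention
        for "default" PLS preprocessing).
    random_state : int, default 0
        Seeds the CV fold shuffle.

    Attributes
    ----------
    n_components_ : selected component count
    cv_rmse_ : ndarray of CV RMSE per candidate count (index 0 = 1 comp)
    pls_ : the fitted underlying PLSRegression
    feature_names_in_ : column names when fitted on a DataFrame
    """

    def __init__(self, max_components=None, cv_folds: int = 10, scale: bool = True,
                 random_state: int = 0):
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.scale = scale
        self.random_state = random_state

    def fit(self, X, y):
        X, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n <= self.cv_folds:
            raise ValueError(f"need more than cv_folds={self.cv_folds} samples, got {n}")
        if p < 1 or np.all(X.std(axis=0) == 0):
            raise DegenerateDesignError("design matrix has no varying feature")
        cap = min(p, n - 1)
        if self.max_components is not None:
            cap = min(cap, self.max_components)

        folds = KFold(self.cv_folds, shuffle=True, random_state=self.random_state)
        split = list(folds.split(X))
        cv_rmse = np.empty(cap)
        for k in range(1, cap + 1):
            sq = 0.0
            for tr, te in split:
                model = PLSRegression(n_components=k, scale=self.scale)
                model.fit(X[tr], y[tr])
                resid = y[te] - model.predict(X[te]).ravel()
                sq += float(resid @ resid)
            cv_rmse[k - 1] = np.sqrt(sq / n)
        self.cv_rmse_ = cv_rmse
        # parsimony tie-break: the fewest components whose CV RMSE is within
        # numerical tolerance of the minimum
        min_rmse = float(cv_rmse.min())
        tol = min_rmse + max(1e-10, 1e-6 * min_rmse)
        self.n_components_ = int(np.argmax(cv_rmse <= tol)) + 1
        self.pls_ = PLSRegression(n_components=self.n_components_, scale=self.scale)
        self.pls_.fit(X, y)
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "pls_")
        X, names = _as_matrix(X)
        if names is not None and hasattr(self, "feature_names_in_"):
            if list(names) != list(self.feature_names_in_):
                raise ValueError(
                    "feature columns differ from training: "
                    f"got {names}, expected {list(self.feature_names_in_)}"
                )
        return self.pls_.predict(X).ravel()


def fit_plsr(table, y, cv_folds: int = 10, seed: int = 0, **kwargs) -> PLSRegressorCV:
    """Fit a :class:`PLSRegressorCV` on a feature table."""
    return PLSRegressorCV(cv_folds=cv_folds, random_state=seed, **kwargs).fit(table, y)
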