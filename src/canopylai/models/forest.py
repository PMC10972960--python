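"""Random-forest LAI regression with the study's hyperparameters.

1000 trees; at each split the forest considers mtry = max(1, floor(p/3))
candidate features — the classical regression-forest default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor


def mtry_default(n_features: int) -> int:
    """Regression-forest split-candidate count: max(1, floor(p/3))."""
    return max(1, n_features // 3)


def lai_random_forest(n_features: int, n_trees: int = 1000, seed: int = 0) -> RandomForestRegressor:
    """Unfitted forest configured for LAI inversion on p features."""
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry_default(n_features),
        random_state=seed,
        oob_score=True,
        n_jobs=1,
    )


def fit_rf(table, y, n_trees: int = 1000, seed: int = 0) -> RandomForestRegressor:
    """Fit the study-configured random forest on a feature table."""
    X = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, float)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 5:
        raise ValueError("random forest needs at least 5 samples")
    forest = lai_random_forest(X.shape[1], n_trees=n_trees, seed=seed)
    forest.fit(X, y)
    return forest
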