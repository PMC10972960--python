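"""Split bookkeeping, augmentation, standardization and the three models."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

from canopylai.config import SplitSpec
from canopylai.models import CNNRegressor, PLSRegressorCV, fit_plsr, fit_rf
from canopylai.models.cnn import InputShapeError
from canopylai.models.forest import mtry_default
from canopylai.raster import PatchSet
from canopylai.splits import (
    DegenerateBandError,
    PatchStandardizer,
    augment_patches,
    split_samples,
    standardize_bands,
)


def make_patchset(n=6, seed=0):
    rng = np.random.default_rng(seed)
    return PatchSet(
        patches=rng.random((n, 32, 32, 5)),
        lai=rng.uniform(1, 6, n),
        ids=np.arange(1, n + 1),
    )


@pytest.mark.parametrize("n,expected_trainval", [(234, 164), (10, 7), (100, 70)])
def test_split_counts_round_half_up(n, expected_trainval):
    trainval, test = split_samples(np.arange(n), SplitSpec(seed=0))
    assert len(trainval) == expected_trainval
    assert len(test) == n - expected_trainval
    assert set(trainval) | set(test) == set(range(n))
    assert not set(trainval) & set(test)


def test_split_deterministic():
    a = split_samples(np.arange(50), SplitSpec(seed=3))
    b = split_samples(np.arange(50), SplitSpec(seed=3))
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_augmentation_sixfold_with_provenance():
    ps = make_patchset(164)
    aug = augment_patches(ps)
    assert len(aug) == 984
    np.testing.assert_array_equal(aug.lai, np.tile(ps.lai, 6))
    # provenance: each source id appears exactly 6 times
    ids, counts = np.unique(aug.source_ids, return_counts=True)
    assert set(counts) == {6}


def test_augmentation_group_identities():
    ps = make_patchset(2)
    p = ps.patches
    rot90 = np.rot90(p, 1, axes=(1, 2))
    # four quarter rotations compose to the identity
    np.testing.assert_array_equal(np.rot90(rot90, 3, axes=(1, 2)), p)
    # flips are involutions
    np.testing.assert_array_equal(p[:, :, ::-1, :][:, :, ::-1, :], p)
    np.testing.assert_array_equal(p[:, ::-1, :, :][:, ::-1, :, :], p)


def test_augmentation_preserves_pixel_statistics():
    """Rotations/flips permute pixels, so any per-patch mean is unchanged."""
    ps = make_patchset(5, seed=2)
    aug = augment_patches(ps)
    nir, red = aug.patches[:, :, :, 4], aug.patches[:, :, :, 2]
    ndvi_mean = ((nir - red) / (nir + red)).mean(axis=(1, 2))
    base = ndvi_mean[: len(ps)]
    for k in range(6):
        np.testing.assert_allclose(ndvi_mean[k * len(ps) : (k + 1) * len(ps)], base)


def test_standardizer_contracts():
    rng = np.random.default_rng(1)
    pool = rng.normal(0.3, 0.05, size=(40, 32, 32, 5)) + np.arange(5) * 0.1
    std, state = standardize_bands(pool)
    np.testing.assert_allclose(std.mean(axis=(0, 1, 2)), 0, atol=1e-9)
    np.testing.assert_allclose(std.std(axis=(0, 1, 2)), 1, atol=1e-9)
    # applying training state to new data generally gives nonzero mean
    other = rng.normal(0.6, 0.05, size=(10, 32, 32, 5))
    std_other, _ = standardize_bands(other, state)
    assert np.abs(std_other.mean()) > 0.1
    # exact round trip
    np.testing.assert_allclose(state.inverse_transform(std), pool, atol=1e-12)


def test_standardizer_rejects_constant_band():
    pool = np.random.default_rng(0).random((5, 32, 32, 5))
    pool[:, :, :, 2] = 0.4
    with pytest.raises(DegenerateBandError):
        PatchStandardizer().fit(pool)


# ---------------------------------------------------------------- PLSR


def test_plsr_single_feature_equals_simple_regression():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1, 40).reshape(-1, 1)
    y = 3 * x.ravel() + 1 + rng.normal(0, 0.05, 40)
    model = PLSRegressorCV(cv_folds=5, random_state=0).fit(x, y)
    assert model.n_components_ == 1
    ols = LinearRegression().fit(x, y)
    np.testing.assert_allclose(model.predict(x), ols.predict(x), atol=1e-8)


def test_plsr_recovers_low_rank_linear_signal():
    """A 3-feature linear target is fit almost perfectly well below full rank.

    PLS components maximize covariance, so finite-sample correlation with
    the noise columns leaks into the early components and a handful of
    extra components beyond the true rank genuinely reduce CV RMSE; the
    selection must still stop short of the full 13 and fit essentially all
    of the signal.
    """
    rng = np.random.default_rng(4)
    n = 80
    basis = rng.normal(size=(n, 3))
    y = basis @ np.array([2.0, -1.0, 0.5]) + rng.normal(0, 0.05, n)
    noise = rng.normal(size=(n, 10)) * 0.5
    X = np.hstack([basis, noise])
    model = PLSRegressorCV(cv_folds=5, random_state=1).fit(X, y)
    assert model.n_components_ < X.shape[1]
    resid = y - model.predict(X)
    r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    assert r2 > 0.999
    # the CV curve has captured the signal by the selected count: no later
    # candidate improves RMSE by more than 1%
    best = model.cv_rmse_.min()
    assert model.cv_rmse_[model.n_components_ - 1] <= 1.01 * best


def test_plsr_max_components_matches_ols():
    """With full components PLS spans the design, matching least squares."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(50, 4))
    y = rng.normal(size=50)
    pls = PLSRegressorCV(max_components=4, cv_folds=5, random_state=0)
    pls.fit(X, y)
    # force the full-rank fit regardless of what CV picked
    from sklearn.cross_decomposition import PLSRegression

    full = PLSRegression(n_components=4, scale=True).fit(X, y)
    ols = LinearRegression().fit(X, y)
    np.testing.assert_allclose(full.predict(X).ravel(), ols.predict(X), atol=1e-6)


def test_plsr_component_choice_stable_under_sample_permutation():
    """Reordering samples only reshuffles CV folds, not the typical choice."""
    rng = np.random.default_rng(6)
    X = rng.normal(size=(60, 5))
    y = X[:, 0] * 2 + rng.normal(0, 0.1, 60)
    chosen, chosen_perm = [], []
    for seed in range(20):
        model = PLSRegressorCV(cv_folds=5, random_state=seed).fit(X, y)
        chosen.append(model.n_components_)
        perm = np.random.default_rng(seed).permutation(60)
        model_p = PLSRegressorCV(cv_folds=5, random_state=seed).fit(X[perm], y[perm])
        chosen_perm.append(model_p.n_components_)
    assert set(chosen) == set(chosen_perm)
    assert abs(np.mean(chosen) - np.mean(chosen_perm)) <= 0.5


# ---------------------------------------------------------------- RF


def test_mtry_default_floor_rule():
    assert mtry_default(19) == 6
    assert mtry_default(3) == 1
    assert mtry_default(2) == 1


def test_rf_deterministic_and_oob_near_zero_on_noise():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(100, 6)), columns=list("abcdef"))
    y = rng.normal(size=100)  # pure noise target
    model = fit_rf(X, y, n_trees=300, seed=1)
    model2 = fit_rf(X, y, n_trees=300, seed=1)
    np.testing.assert_array_equal(model.predict(X.to_numpy()), model2.predict(X.to_numpy()))
    assert abs(model.oob_score_) < 0.15


def test_rf_prediction_within_training_range():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(60, 4))
    y = rng.uniform(2, 4, 60)
    model = fit_rf(X, y, n_trees=100, seed=0)
    preds = model.predict(X)
    assert preds.min() >= 2 and preds.max() <= 4


# ---------------------------------------------------------------- CNN


def test_cnn_shape_trace_matches_architecture():
    trace = dict(CNNRegressor().shape_trace())
    assert trace["conv1"] == (16, 32, 32)
    assert trace["batchnorm1"] == (16, 32, 32)
    assert trace["pool1"] == (16, 16, 16)
    assert trace["conv2"] == (32, 16, 16)
    assert trace["pool2"] == (32, 8, 8)
    assert trace["conv3"] == (64, 8, 8)
    assert trace["pool3"] == (64, 4, 4)
    assert trace["conv4"] == (128, 4, 4)
    assert trace["pool4"] == (128, 2, 2)
    assert trace["dropout"] == (128, 2, 2)
    assert trace["flatten"] == (512,)
    assert trace["dense1"] == (64,)
    assert trace["dense2"] == (1,)


def test_cnn_forward_shapes_at_runtime():
    """The actual network reproduces the declared trace layer by layer."""
    from canopylai.models._nn import ReLU
    from canopylai.models.cnn import build_cnn, shape_trace

    net = build_cnn(seed=0)
    x = np.random.default_rng(0).random((2, 5, 32, 32)).astype(np.float32)
    expected = [s for _, s in shape_trace()]
    got = []
    for layer in net.layers:
        x = layer.forward(x, training=False)
        if not isinstance(layer, ReLU):  # activations keep their input shape
            got.append(x.shape[1:])
    assert got == expected


def test_cnn_rejects_wrong_patch_shape():
    with pytest.raises(InputShapeError):
        CNNRegressor(epochs=1).fit(np.zeros((4, 16, 16, 5)), np.zeros(4))


def test_cnn_eval_mode_deterministic():
    rng = np.random.default_rng(9)
    X = rng.random((30, 32, 32, 5))
    y = rng.uniform(1, 6, 30)
    model = CNNRegressor(epochs=2, patience=None, val_fraction=0.2, random_state=0).fit(X, y)
    p1, p2 = model.predict(X), model.predict(X)
    np.testing.assert_array_equal(p1, p2)


def test_cnn_fit_deterministic_for_fixed_seed():
    rng = np.random.default_rng(10)
    X = rng.random((24, 32, 32, 5))
    y = rng.uniform(1, 6, 24)
    a = CNNRegressor(epochs=2, patience=None, random_state=5).fit(X, y).predict(X)
    b = CNNRegressor(epochs=2, patience=None, random_state=5).fit(X, y).predict(X)
    np.testing.assert_array_equal(a, b)


def test_cnn_can_overfit_tiny_dataset():
    """Capacity check: with dropout off, 20 patches are memorized."""
    rng = np.random.default_rng(11)
    lai = rng.uniform(1, 6, 20)
    # patches whose band levels encode the label, plus texture noise
    X = rng.normal(0, 0.02, size=(20, 32, 32, 5)) + lai[:, None, None, None] / 10.0
    model = CNNRegressor(
        epochs=150, patience=None, val_fraction=0.0, dropout=0.0, lr=0.003,
        batch_size=10, random_state=0,
    )
    model.fit(X, lai)
    rmse = float(np.sqrt(np.mean((model.predict(X) - lai) ** 2)))
    assert rmse < 0.1
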