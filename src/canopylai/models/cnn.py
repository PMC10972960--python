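"""CNN regression of LAI from standardized 32x32x5 multispectral patches.

Architecture (four conv blocks, each conv -> batch-norm -> ReLU -> 2x2
max-pool, with same padding forcing the spatial sizes):

    input  5 x 32 x 32
    block1 16 x 32 x 32 -> pool -> 16 x 16 x 16
    block2 32 x 16 x 16 -> pool -> 32 x 8 x 8
    block3 64 x 8 x 8   -> pool -> 64 x 4 x 4
    block4 128 x 4 x 4  -> pool -> 128 x 2 x 2
    dropout(p=0.2) -> flatten 512 -> dense 64 (ReLU) -> dense 1

trained with mini-batch SGD with momentum (lr 0.001) on an MSE loss,
keeping the weights of the best validation epoch (early stopping).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ..config import round_half_up
from ..splits import PatchStandardizer
from ._nn import BatchNorm, Conv3x3, Dense, Dropout, Flatten, MaxPool2, ReLU, Sequential

#: (block index, output channels) of the four convolutional blocks
BLOCK_FILTERS = (16, 32, 64, 128)

PATCH_SHAPE = (32, 32, 5)


class InputShapeError(ValueError):
    """Raised for patch arrays that are not N x 32 x 32 x 5."""


def _check_patches(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 4 or X.shape[1:] != PATCH_SHAPE:
        raise InputShapeError(f"expected patches of shape (N, {PATCH_SHAPE}), got {X.shape}")
    return X


def _to_nchw(X: np.ndarray) -> np.ndarray:
    # float32 layout: the network trains in single precision
    return np.ascontiguousarray(X.transpose(0, 3, 1, 2), dtype=np.float32)


def build_cnn(dropout: float = 0.2, seed: int = 0) -> Sequential:
    """Assemble the (untrained) four-block patch-regression network."""
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(rng.integers(2**31))
    layers = []
    c_in = PATCH_SHAPE[2]
    for c_out in BLOCK_FILTERS:
        layers += [Conv3x3(c_in, c_out, rng), BatchNorm(c_out), ReLU(), MaxPool2()]
        c_in = c_out
    layers += [
        Dropout(dropout, drop_rng),
        Flatten(),
        Dense(BLOCK_FILTERS[-1] * 2 * 2, 64, rng),
        ReLU(),
        Dense(64, 1, rng),
    ]
    return Sequential(layers)


def shape_trace(n_channels_in: int = 5, size: int = 32) -> list[tuple[str, tuple]]:
    """Layer-by-layer output tensor shapes (channels, height, width).

    Running the architecture symbolically; the final entries are the
    flatten width, the hidden dense width and the scalar output.
    """
    trace = []
    h = size
    for bi, c in enumerate(BLOCK_FILTERS, start=1):
        trace.append((f"conv{bi}", (c, h, h)))
        trace.append((f"batchnorm{bi}", (c, h, h)))
        h //= 2
        trace.append((f"pool{bi}", (c, h, h)))
    trace.append(("dropout", (BLOCK_FILTERS[-1], h, h)))
    trace.append(("flatten", (BLOCK_FILTERS[-1] * h * h,)))
    trace.append(("dense1", (64,)))
    trace.append(("dense2", (1,)))
    return trace


class CNNRegressor(RegressorMixin, BaseEstimator):
    """Patch-based CNN LAI regressor with a scikit-learn interface.

    ``fit(X, y)`` expects raw reflectance patches of shape (N, 32, 32, 5);
    per-band standardization is fitted internally on the training pool and
    reapplied at prediction time.  A validation subset (``val_fraction``)
    monitors MSE for early stopping; the best-validation weights are
    restored after training.  Pass ``X_val``/``y_val`` to supply an
    explicit validation set instead.

    Parameters
    ----------
    epochs : int, default 60
        Maximum training epochs.
    batch_size : int, default 32
    lr : float, default 0.001
        SGD learning rate.
    momentum : float, default 0.9
    dropout : float, default 0.2
        Dropout probability after the fourth block (training only).
    patience : int or None, default 10
        Early-stopping patience on validation MSE; None disables.
    val_fraction : float, default 0.2
        Fraction of ``fit`` samples held out for validation when no
        explicit validation set is given (count is round-half-up, so a
        984-patch pool splits 787/197).
    standardize : bool, default True
    random_state : int, default 0

    Attributes
    ----------
    net_ : the trained :class:`Sequential` network
    standardizer_ : fitted :class:`PatchStandardizer` (or None)
    history_ : DataFrame of per-epoch train/validation MSE
    best_epoch_, n_epochs_trained_ : ints
    """

    def __init__(
        self,
        epochs: int = 60,
        batch_size: int = 32,
        lr: float = 0.001,
        momentum: float = 0.9,
        dropout: float = 0.2,
        patience: int | None = 10,
        val_fraction: float = 0.2,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.momentum = momentum
        self.dropout = dropout
        self.patience = patience
        self.val_fraction = val_fraction
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X = _check_patches(X)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.random_state)

        if X_val is None and self.val_fraction > 0:
            n_train = round_half_up(len(X) * (1 - self.val_fraction))
            order = rng.permutation(len(X))
            tr, va = order[:n_train], order[n_train:]
            X, X_val, y, y_val = X[tr], X[va], y[tr], y[va]
        elif X_val is not None:
            X_val = _check_patches(X_val)
            y_val = np.asarray(y_val, dtype=float).ravel()

        if self.standardize:
            self.standardizer_ = PatchStandardizer().fit(X)
            X = self.standardizer_.transform(X)
            if X_val is not None:
                X_val = self.standardizer_.transform(X_val)
        else:
            self.standardizer_ = None

        Xn = _to_nchw(X)
        Xv = _to_nchw(X_val) if X_val is not None else None
        self.net_ = build_cnn(dropout=self.dropout, seed=int(rng.integers(2**31)))

        history = []
        best_val = np.inf
        best_state = self.net_.state()
        best_epoch = 0
        stale = 0
        n = len(Xn)
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            train_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xn[idx], y[idx]
                pred = self.net_.forward(xb, training=True).ravel()
                resid = pred - yb
                train_loss += float(resid @ resid)
                self.net_.backward((2.0 * resid / len(idx)).reshape(-1, 1).astype(np.float32))
                self.net_.sgd_step(self.lr, self.momentum)
            train_mse = train_loss / n
            if Xv is not None and len(Xv):
                val_mse = float(np.mean((self._forward_eval(Xv) - y_val) ** 2))
            else:
                val_mse = train_mse
            history.append({"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse})
            if val_mse < best_val - 1e-12:
                best_val, best_epoch, stale = val_mse, epoch, 0
                best_state = self.net_.state()
            else:
                stale += 1
                if self.patience is not None and stale >= self.patience:
                    break
        self.net_.load_state(best_state)
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        self.n_epochs_trained_ = len(history)
        return self

    def _forward_eval(self, Xn: np.ndarray, batch: int = 256) -> np.ndarray:
        out = np.empty(len(Xn))
        for start in range(0, len(Xn), batch):
            out[start : start + batch] = self.net_.forward(
                Xn[start : start + batch], training=False
            ).ravel()
        return out

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = _check_patches(X)
        if self.standardizer_ is not None:
            X = self.standardizer_.transform(X)
        return self._forward_eval(_to_nchw(X))

    def shape_trace(self) -> list[tuple[str, tuple]]:
        """Output tensor shape after every layer for a 32x32x5 input."""
        return shape_trace()


def train_cnn(patches, y, val_patches=None, val_y=None, **params) -> CNNRegressor:
    """Functional wrapper: fit a :class:`CNNRegressor` on patch arrays."""
    model = CNNRegressor(**params)
    return model.fit(patches, y, X_val=val_patches, y_val=val_y)
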