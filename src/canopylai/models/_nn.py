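"""Minimal NumPy neural-network layers with explicit backpropagation.

Supports exactly what the LAI patch regressor needs: 3x3 same-padding
convolutions (im2col), batch normalization, ReLU, 2x2 max pooling,
inverted dropout, flatten and dense layers, trained by mini-batch SGD
with momentum on an MSE loss.  Data layout is NCHW throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: forward/backward plus (param, grad, name) triples."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return []


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same (zero) padding, He-normal init."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        padded = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # (n, c, h, w, 3, 3) -> (n, h*w, c*9)
        win = sliding_window_view(padded, (3, 3), axis=(2, 3))
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * 9)

    def forward(self, x, training):
        self.x_shape = x.shape
        self.cols = self._im2col(x)
        n, _, h, w = x.shape
        out = self.cols @ self.w.T + self.b
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, grad):
        n, _, h, w = self.x_shape
        g = grad.reshape(n, self.c_out, h * w).transpose(0, 2, 1)  # (n, hw, c_out)
        self.dw = np.tensordot(g, self.cols, axes=([0, 1], [0, 1]))
        self.db = g.sum(axis=(0, 1))
        dcols = g @ self.w  # (n, hw, c_in*9)
        dcols = dcols.reshape(n, h, w, self.c_in, 3, 3)
        dpad = np.zeros((n, self.c_in, h + 2, w + 2), dtype=dcols.dtype)
        for dr in range(3):
            for dc in range(3):
                dpad[:, :, dr : dr + h, dc : dc + w] += dcols[:, :, :, :, dr, dc].transpose(
                    0, 3, 1, 2
                )
        return dpad[:, :, 1 : 1 + h, 1 : 1 + w]

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class BatchNorm(Layer):
    """Per-channel batch normalization with running inference statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros(channels, dtype=np.float32)
        self.dbeta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        axes = (0, 2, 3)
        shape = (1, -1, 1, 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean.reshape(shape)) * self.inv_std.reshape(shape)
        self.m = x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma.reshape(shape) * self.xhat + self.beta.reshape(shape)

    def backward(self, grad):
        shape = (1, -1, 1, 1)
        axes = (0, 2, 3)
        self.dgamma = (grad * self.xhat).sum(axis=axes)
        self.dbeta = grad.sum(axis=axes)
        gxhat = grad * self.gamma.reshape(shape)
        return (
            self.inv_std.reshape(shape)
            / self.m
            * (
                self.m * gxhat
                - gxhat.sum(axis=axes).reshape(shape)
                - self.xhat * (gxhat * self.xhat).sum(axis=axes).reshape(shape)
            )
        )

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class ReLU(Layer):
    def forward(self, x, training):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class MaxPool2(Layer):
    """2x2 max pooling; gradients split equally among tied maxima."""

    def forward(self, x, training):
        n, c, h, w = x.shape
        self.x_shape = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = blocks.max(axis=(3, 5))
        self.tie_mask = blocks == out[:, :, :, None, :, None]
        self.tie_count = self.tie_mask.sum(axis=(3, 5), dtype=x.dtype)
        return out

    def backward(self, grad):
        n, c, h, w = self.x_shape
        share = (grad / self.tie_count)[:, :, :, None, :, None]
        return (self.tie_mask * share).reshape(n, c, h, w)


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0:
            self.mask = None
            return x
        self.mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


class Flatten(Layer):
    def forward(self, x, training):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.x_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self.x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = self.x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T


class Sequential:
    """A feed-forward chain with SGD-momentum training state."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self._velocity: dict[int, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def sgd_step(self, lr: float, momentum: float) -> None:
        idx = 0
        for layer in self.layers:
            for _, param, grad in layer.params():
                v = self._velocity.setdefault(idx, np.zeros_like(param))
                v *= momentum
                v -= lr * grad
                param += v
                idx += 1

    def state(self) -> list:
        """Deep copy of all parameters and batch-norm running statistics."""
        snap = []
        for layer in self.layers:
            entry = {name: param.copy() for name, param, _ in layer.params()}
            if isinstance(layer, BatchNorm):
                entry["running_mean"] = layer.running_mean.copy()
                entry["running_var"] = layer.running_var.copy()
            snap.append(entry)
        return snap

    def load_state(self, snap: list) -> None:
        for layer, entry in zip(self.layers, snap):
            for name, param, _ in layer.params():
                param[...] = entry[name]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = entry["running_mean"]
                layer.running_var[...] = entry["running_var"]
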