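"""Minimal 1-D neural-network engine: layers, manual backprop, Adam.

Everything operates on float32 arrays of shape (batch, channels, length).
Convolutions use "same"-style padding with ceil-mode length arithmetic
(output length = ceil(input length / stride)), which is what the network
architecture's printed feature-map sizes require. Layers cache what their
backward pass needs; calling ``backward`` before ``forward`` is an error.

This is deliberately small: just the pieces the multi-scale residual
classifier uses, fast enough on one CPU at the segment sizes involved
(im2col + matmul convolutions).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Parameter", "Conv1d", "BatchNorm1d", "ReLU", "MaxPool1d",
           "GlobalAvgPool1d", "Dropout", "Linear", "Adam",
           "conv_output_length", "softmax"]


def conv_output_length(length: int, stride: int) -> int:
    """Ceil-mode same-padded output length."""
    return -(-length // stride)


def _same_padding(length: int, kernel: int, stride: int) -> tuple[int, int]:
    out = conv_output_length(length, stride)
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of (batch, classes) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Parameter:
    """Trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []


class Conv1d(Layer):
    """Same-padded 1-D convolution, no bias (a norm layer always follows)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator, name: str = "conv"):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       size=(out_channels, fan_in))
        self.weight = Parameter(w, name=f"{name}.weight")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight]

    def _im2col(self, xp: np.ndarray, out_len: int) -> np.ndarray:
        n, c, _ = xp.shape
        cols = np.empty((n, c, self.kernel, out_len), dtype=xp.dtype)
        base = self.stride * np.arange(out_len)
        for j in range(self.kernel):
            cols[:, :, j, :] = xp[:, :, base + j]
        return cols.reshape(n, c * self.kernel, out_len)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        left, right = _same_padding(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        out_len = conv_output_length(length, self.stride)
        cols = self._im2col(xp, out_len)
        y = np.matmul(self.weight.value, cols)
        self._cache = (cols, length, left)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, length, left = self._cache
        n = dy.shape[0]
        self.weight.grad += np.einsum("nfl,ncl->fc", dy, cols,
                                      optimize=True).astype(np.float32)
        dcols = np.matmul(self.weight.value.T, dy)
        dcols = dcols.reshape(n, self.in_channels, self.kernel, -1)
        out_len = dcols.shape[-1]
        pad_len = length + sum(_same_padding(length, self.kernel, self.stride))
        dxp = np.zeros((n, self.in_channels, pad_len), dtype=dy.dtype)
        base = self.stride * np.arange(out_len)
        for j in range(self.kernel):
            np.add.at(dxp, (slice(None), slice(None), base + j),
                      dcols[:, :, j, :])
        return dxp[:, :, left:left + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, name: str = "bn"):
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None] * xhat \
            + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[2]
        self.gamma.grad += np.sum(dy * xhat, axis=(0, 2)).astype(np.float32)
        self.beta.grad += np.sum(dy, axis=(0, 2)).astype(np.float32)
        g = self.gamma.value[None, :, None] * inv_std[None, :, None]
        mean_dy = dy.mean(axis=(0, 2))[None, :, None]
        mean_dy_xhat = (dy * xhat).mean(axis=(0, 2))[None, :, None]
        return g * (dy - mean_dy - xhat * mean_dy_xhat) if m > 1 \
            else g * dy  # degenerate single-element batch: no centering


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Same-padded max pooling with ceil-mode lengths."""

    def __init__(self, kernel: int = 3, stride: int = 2):
        self.kernel = kernel
        self.stride = stride
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        left, right = _same_padding(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)),
                    constant_values=-np.inf)
        out_len = conv_output_length(length, self.stride)
        base = self.stride * np.arange(out_len)
        windows = np.stack([xp[:, :, base + j] for j in range(self.kernel)],
                           axis=2)  # (n, c, k, out)
        arg = windows.argmax(axis=2)
        y = np.take_along_axis(windows, arg[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (arg, length, left, xp.shape[-1], base)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, length, left, pad_len, base = self._cache
        n, c, out_len = dy.shape
        dxp = np.zeros((n, c, pad_len), dtype=dy.dtype)
        pos = arg + base[None, None, :]
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dxp, (ni, ci, pos), dy)
        return dxp[:, :, left:left + length]


class GlobalAvgPool1d(Layer):
    """(n, c, l) → (n, c) mean over time."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._length, axis=2) / self._length


class Dropout(Layer):
    """Inverted dropout; identity when not training."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str = "fc"):
        bound = math.sqrt(1.0 / in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_features, in_features)),
            name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_features), name=f"{name}.bias")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += (dy.T @ x).astype(np.float32)
        self.bias.grad += dy.sum(axis=0).astype(np.float32)
        return dy @ self.weight.value


class Adam:
    """Adaptive-moment optimizer with the standard bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad ** 2 - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
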