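"""Minimal NCHW convolutional-network engine on numpy.

Implements exactly the layer set the crown-segmentation architecture needs —
strided convolution (im2col + BLAS matmul), batch normalization, ReLU, 2x2
max pooling, 2x2 stride-2 transposed convolution, residual addition and
channel concatenation — with hand-written backward passes and an Adam
optimizer.  Everything is float32 and deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """k x k convolution with stride and symmetric zero padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.w = Param(he_init(rng, (c_out, c_in, k, k), fan_in=c_in * k * k))
        self.b = Param(np.zeros(c_out, dtype=np.float32)) if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train):
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        # windows: (N, C, Ho, Wo, k, k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        y = np.tensordot(win, self.w.value, axes=([1, 4, 5], [1, 2, 3]))
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        if train:
            self._cache = (x.shape, xp.shape, win)
        return y

    def backward(self, gout):
        x_shape, xp_shape, win = self._cache
        p, k, s = self.pad, self.k, self.stride
        n, c_out, ho, wo = gout.shape
        # dW: correlate stored windows with the output gradient
        self.w.grad += np.tensordot(
            gout, win, axes=([0, 2, 3], [0, 2, 3])
        )
        if self.b is not None:
            self.b.grad += gout.sum(axis=(0, 2, 3))
        dxp = np.zeros(xp_shape, dtype=np.float32)
        w = self.w.value
        for ki in range(k):
            for kj in range(k):
                # each kernel tap scatters gout back onto a strided slice
                contrib = np.tensordot(gout, w[:, :, ki, kj], axes=([1], [0]))
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += (
                    contrib.transpose(0, 3, 1, 2)
                )
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat
        y += self.beta.value[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return y.astype(np.float32)

    def backward(self, gout):
        xhat, inv_std = self._cache
        n, c, h, w = gout.shape
        m = n * h * w
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        sum_g = gout.sum(axis=(0, 2, 3), keepdims=False)[None, :, None, None]
        sum_gx = (gout * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (g * inv_std[None, :, None, None] / m) * (
            m * gout - sum_g - xhat * sum_gx
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, gout):
        return gout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even).

    Gradient routes to exactly one argmax per window (first occurrence), so
    tied maxima — common after ReLU zeros — are not double-counted.
    """

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = np.ascontiguousarray(
            x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        ).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return y

    def backward(self, gout):
        n, c, h, w = self._shape
        g4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(g4, self._idx[..., None],
                          gout[..., None].astype(np.float32), axis=-1)
        g = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(g).reshape(n, c, h, w)


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (exact spatial doubling)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.w = Param(he_init(rng, (c_in, c_out, 2, 2), fan_in=c_in))
        self.b = Param(np.zeros(c_out, dtype=np.float32)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train):
        n, c, h, w = x.shape
        y = np.einsum("nchw,coij->nohiwj", x, self.w.value, optimize=True)
        y = y.reshape(n, -1, 2 * h, 2 * w)
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        if train:
            self._x = x
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, gout):
        x = self._x
        n, c_out, h2, w2 = gout.shape
        g6 = gout.reshape(n, c_out, h2 // 2, 2, w2 // 2, 2).transpose(
            0, 1, 2, 4, 3, 5
        )  # (n, o, h, w, i, j)
        self.w.grad += np.einsum("nohwij,nchw->coij", g6, x, optimize=True)
        if self.b is not None:
            self.b.grad += gout.sum(axis=(0, 2, 3))
        dx = np.einsum("nohwij,coij->nchw", g6, self.w.value, optimize=True)
        return np.ascontiguousarray(dx, dtype=np.float32)


class Adam:
    """Adaptive-moment optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-pixel binary cross-entropy on logits; returns (mean loss, dL/dz)."""
    z = z.astype(np.float64)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = (sig - t) / z.size
    return float(loss.mean()), grad.astype(np.float32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
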