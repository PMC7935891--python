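"""Minimal CNN building blocks on numpy with hand-written backpropagation.

Layers operate on float32 arrays in NCHW layout. Each layer caches what its
backward pass needs during forward; `backward` consumes the upstream gradient
and returns the gradient with respect to the layer input. Trainable arrays
and their gradients are exposed through ``params()`` as (name, value, grad)
triples so optimizers can update them in place.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless layers only need forward/backward."""

    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """3x3 (or kxk) convolution with 'same' zero padding, stride 1.

    Implemented as im2col + matmul; the backward col2im scatter is unrolled
    over the k*k kernel offsets, which keeps it vectorized over pixels.
    """

    def __init__(self, in_channels, out_channels, kernel_size=3, rng=None):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.ci = int(in_channels)
        self.co = int(out_channels)
        self.k = int(kernel_size)
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = self.ci * self.k * self.k
        self.w = _he_init(rng, (self.co, fan_in), fan_in)
        self.b = np.zeros(self.co, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if c != self.ci:
            raise ValueError(f"expected {self.ci} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # windows: (n, c, h, w, k, k) -> cols (n*h*w, c*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = cols @ self.w.T + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, self.co).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, co, h, w = grad.shape
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * h * w, co)
        g2 = np.ascontiguousarray(g2)
        self.gw[...] = g2.T @ self._cols
        self.gb[...] = g2.sum(axis=0)
        gcols = g2 @ self.w  # (n*h*w, ci*k*k)
        gcols = gcols.reshape(n, h, w, self.ci, self.k, self.k)
        p = self.k // 2
        gx = np.zeros((n, self.ci, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                gx[:, :, i:i + h, j:j + w] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return gx[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2. Input spatial dims must be even."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        g = self._mask * grad[:, :, :, None, :, None]
        return g.reshape(n, c, h, w)


class UpsampleNearest2d(Layer):
    """Nearest-neighbor 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), self._shape
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = _he_init(rng, (out_features, in_features), in_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.gw[...] = grad.T @ self._x
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
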