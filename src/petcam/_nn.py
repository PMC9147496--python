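"""Minimal reverse-mode neural-network layers on numpy.

Implements exactly the pieces the MIP classifier and the 3D outcome
network need: 2D/3D convolutions (im2col + BLAS matmul), dense layers,
ReLU/ELU, inverted dropout, 2x2x2 max pooling and Adam.  Every layer
caches its forward pass and exposes ``backward(dout, accumulate=...)``;
with ``accumulate=False`` the pass propagates input gradients without
touching parameter gradients, which is how per-sample feature-map
influences (the CAM weights) are obtained without corrupting training
gradients.

All arithmetic is float64: the gradient correctness contract is checked
against central finite differences, and float32 would drown the
comparison in rounding noise.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "Conv3d",
    "Dense",
    "ReLU",
    "ELU",
    "Dropout",
    "Flatten",
    "MaxPool3d",
    "Sequential",
    "Adam",
    "sigmoid",
]


def sigmoid(x):
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: parameter/gradient dicts plus cached forward state."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout, accumulate=True):  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """3x3 (by default) convolution with zero padding, arbitrary stride."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=1, *, rng):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        self.params["W"] = _he_init(rng, (fan_in, c_out), fan_in)
        self.params["b"] = np.zeros(c_out)
        self.zero_grad()
        self._cache = None

    def out_shape(self, h, w):
        k, s, p = self.k, self.stride, self.pad
        return ((h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv2d expected {self.c_in} channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (b, c, ho, wo, k, k) -> (b, ho*wo, c*k*k)
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b, ho * wo, c * k * k
        )
        out = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(b, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout, accumulate=True):
        cols, x_shape, ho, wo = self._cache
        b, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        d2 = dout.transpose(0, 2, 3, 1).reshape(b, ho * wo, self.c_out)
        if accumulate:
            self.grads["W"] += np.tensordot(cols, d2, axes=([0, 1], [0, 1]))
            self.grads["b"] += d2.sum(axis=(0, 1))
        dcols = (d2 @ self.params["W"].T).reshape(b, ho, wo, c, k, k)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += (
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                )
        return dxp[:, :, p : p + h, p : p + w]


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, zero padding 1."""

    def __init__(self, c_in, c_out, kernel=3, pad=1, *, rng):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.k, self.pad = kernel, pad
        fan_in = c_in * kernel**3
        self.params["W"] = _he_init(rng, (fan_in, c_out), fan_in)
        self.params["b"] = np.zeros(c_out)
        self.zero_grad()
        self._cache = None

    def forward(self, x, train=False):
        b, c, d, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv3d expected {self.c_in} channels, got {c}")
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        do, ho, wo = win.shape[2], win.shape[3], win.shape[4]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            b, do * ho * wo, c * k**3
        )
        out = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, x.shape, do, ho, wo)
        return out.reshape(b, do, ho, wo, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, dout, accumulate=True):
        cols, x_shape, do, ho, wo = self._cache
        b, c, d, h, w = x_shape
        k, p = self.k, self.pad
        d2 = dout.transpose(0, 2, 3, 4, 1).reshape(b, do * ho * wo, self.c_out)
        if accumulate:
            self.grads["W"] += np.tensordot(cols, d2, axes=([0, 1], [0, 1]))
            self.grads["b"] += d2.sum(axis=(0, 1))
        dcols = (d2 @ self.params["W"].T).reshape(b, do, ho, wo, c, k, k, k)
        dxp = np.zeros((b, c, d + 2 * p, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                for kl in range(k):
                    dxp[:, :, ki : ki + do, kj : kj + ho, kl : kl + wo] += (
                        dcols[:, :, :, :, :, ki, kj, kl].transpose(0, 4, 1, 2, 3)
                    )
        return dxp[:, :, p : p + d, p : p + h, p : p + w]


class Dense(Layer):
    def __init__(self, n_in, n_out, *, rng, init_scale=None):
        super().__init__()
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, scale, size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)
        self.zero_grad()
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout, accumulate=True):
        if accumulate:
            self.grads["W"] += self._x.T @ dout
            self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout, accumulate=True):
        return np.where(self._mask, dout, 0.0)


class ELU(Layer):
    def __init__(self, alpha=1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=False):
        self._pos = x > 0
        self._neg_out = self.alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
        return np.where(self._pos, x, self._neg_out)

    def backward(self, dout, accumulate=True):
        return np.where(self._pos, dout, dout * (self._neg_out + self.alpha))


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p, *, rng):
        super().__init__()
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout, accumulate=True):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, accumulate=True):
        return dout.reshape(self._shape)


class MaxPool3d(Layer):
    """Non-overlapping 2x2x2 max pooling; input dims must be even."""

    def forward(self, x, train=False):
        b, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"MaxPool3d needs even spatial dims, got {(d, h, w)}")
        win = x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
        win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            b, c, d // 2, h // 2, w // 2, 8
        )
        self._argmax = win.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(win, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout, accumulate=True):
        b, c, d, h, w = self._in_shape
        dwin = np.zeros((b, c, d // 2, h // 2, w // 2, 8))
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return dwin.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d, h, w)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout, accumulate=True):
        for layer in reversed(self.layers):
            dout = layer.backward(dout, accumulate=accumulate)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append((layer, name))
        return out


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, parameters, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.parameters = list(parameters)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(layer.params[n]) for layer, n in self.parameters]
        self._v = [np.zeros_like(layer.params[n]) for layer, n in self.parameters]

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.parameters):
            g = layer.grads[name]
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for layer, _ in self.parameters:
            layer.zero_grad()
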