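"""Minimal CNN building blocks on numpy arrays.

All tensors are NHWC float32.  Every layer implements ``forward(x, train)``
(caching whatever the backward pass needs) and ``backward(grad)`` which
returns the gradient w.r.t. the layer input and accumulates parameter
gradients in-place.  This is deliberately a small, explicit tape-free
design: the networks in this package (detection and segmentation heads,
a shallow autoencoder) are static graphs that can be walked by hand.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2x2",
    "Dropout",
    "glorot_uniform",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return int(self.value.size)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm moving statistics)."""
        return []

    def n_parameters(self, include_buffers: bool = True) -> int:
        n = sum(p.size for p in self.params())
        if include_buffers:
            n += sum(int(b.size) for b in self.buffers())
        return n

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Conv2d(Layer):
    """k x k convolution, NHWC, zero padding ('same' keeps H,W when stride=1).

    Weight layout is (k*k*c_in, c_out) so the parameter count is
    k^2*c_in*c_out + c_out.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: str | int = "same", rng: np.random.Generator | None = None,
                 init: str = "glorot", init_sigma: float = 0.01,
                 bias_init: float = 0.0):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k // 2 if stride == 1 else 0) if pad == "same" else int(pad)
        fan_in, fan_out = k * k * c_in, k * k * c_out
        if init == "glorot":
            w = glorot_uniform(rng, fan_in, fan_out, (k * k * c_in, c_out))
        elif init == "normal":
            w = rng.normal(0.0, init_sigma, size=(k * k * c_in, c_out)).astype(np.float32)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.w = Param(w)
        self.b = Param(np.full(c_out, bias_init, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _im2col(self, xp: np.ndarray):
        k, s = self.k, self.stride
        v = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N, Ho*, Wo*, C, k, k)
        v = v[:, ::s, ::s]
        v = np.moveaxis(v, 3, 5)  # (N, Ho, Wo, k, k, C)
        n, ho, wo = v.shape[:3]
        return np.ascontiguousarray(v).reshape(n * ho * wo, k * k * self.c_in), (n, ho, wo)

    def forward(self, x, train=False):
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        cols, (n, ho, wo) = self._im2col(xp)
        y = cols @ self.w.value + self.b.value
        self._cache = (cols, xp.shape, (n, ho, wo))
        return y.reshape(n, ho, wo, self.c_out)

    def backward(self, grad):
        cols, xp_shape, (n, ho, wo) = self._cache
        g = grad.reshape(n * ho * wo, self.c_out).astype(np.float32)
        self.w.grad += cols.T @ g
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.w.value.T).reshape(n, ho, wo, self.k, self.k, self.c_in)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + ho * s:s, j:j + wo * s:s, :] += dcols[:, :, :, i, j, :]
        p = self.pad
        if p:
            dxp = dxp[:, p:-p, p:-p, :]
        return dxp


class ConvTranspose2x2(Layer):
    """2x2 stride-2 transposed convolution (exact 2x upsampling, no overlap)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(glorot_uniform(rng, c_in, 4 * c_out, (c_in, 4 * c_out)))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        n, h, w, _ = x.shape
        y = x.reshape(n * h * w, self.c_in) @ self.w.value  # (.., 4*c_out)
        y = y.reshape(n, h, w, 2, 2, self.c_out) + self.b.value
        y = np.moveaxis(y, 3, 2)  # (n, h, 2, w, 2, c)
        self._cache = (x, (n, h, w))
        return np.ascontiguousarray(y).reshape(n, 2 * h, 2 * w, self.c_out)

    def backward(self, grad):
        x, (n, h, w) = self._cache
        g = grad.reshape(n, h, 2, w, 2, self.c_out)
        g = np.moveaxis(g, 2, 3)  # (n, h, w, 2, 2, c)
        g = np.ascontiguousarray(g).reshape(n * h * w, 4 * self.c_out)
        self.b.grad += grad.reshape(-1, self.c_out).sum(axis=0)
        xf = x.reshape(n * h * w, self.c_in)
        self.w.grad += xf.T @ g
        return (g @ self.w.value.T).reshape(n, h, w, self.c_in)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with moving statistics.

    Buffers (moving mean/variance) are counted by ``n_parameters`` when
    ``include_buffers`` is true, giving 4 entries per channel.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.c = c
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.moving_mean = np.zeros(c, dtype=np.float32)
        self.moving_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.moving_mean, self.moving_var]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.moving_mean *= self.momentum
            self.moving_mean += (1 - self.momentum) * mean
            self.moving_var *= self.momentum
            self.moving_var += (1 - self.momentum) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train, x.shape)
        return (xhat * self.gamma.value + self.beta.value).astype(np.float32)

    def backward(self, grad):
        xhat, inv, train, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        gy = grad * self.gamma.value
        if not train:
            return (gy * inv).astype(np.float32)
        # full batch-norm backward
        t1 = gy - gy.mean(axis=(0, 1, 2)) - xhat * (gy * xhat).sum(axis=(0, 1, 2)) / m
        return (t1 * inv).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y.astype(np.float32)

    def backward(self, grad):
        return (grad * self._y * (1.0 - self._y)).astype(np.float32)


class MaxPool2x2(Layer):
    """2x2 stride-2 max pooling; ties share the gradient equally."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        assert h % 2 == 0 and w % 2 == 0, "MaxPool2x2 needs even spatial dims"
        r = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = r.max(axis=(2, 4))
        mask = (r == y[:, :, None, :, None, :])
        self._mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
        self._shape = (n, h, w, c)
        return y

    def backward(self, grad):
        n, h, w, c = self._shape
        g = self._mask * grad[:, :, None, :, None, :]
        return g.reshape(n, h, w, c).astype(np.float32)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        self.p = float(p)
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask
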