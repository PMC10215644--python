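"""Minimal numpy layer library with reverse-mode gradients.

Implements exactly the pieces the MobileNet-style classifier needs:
standard and depthwise 2-D convolutions (im2col based), batch
normalization, ReLU, global average pooling, a dense head and softmax
cross-entropy, plus SGD with momentum. Arrays are NCHW float32.

This is deliberately small: correctness over generality. Gradients of the
convolution layers are exercised against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "DepthwiseConv2D",
    "BatchNorm2D",
    "ReLU",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """x (N,C,H,W) -> columns (N, C*k*k, L) plus output spatial dims."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, ho, wo, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int, ho: int, wo: int):
    """Scatter-add columns back to the (padded) input; inverse of _im2col."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    if pad:
        out = out[:, :, pad : hp - pad, pad : wp - pad]
    return out


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Standard convolution, no bias (batch norm follows)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.k, self.stride, self.pad = k, stride, k // 2
        self.gw = np.zeros_like(self.w)
        self.params, self.grads = [self.w], [self.gw]

    def forward(self, x, train):
        self.x_shape = x.shape
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        self.cols, self.ho, self.wo = cols, ho, wo
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = np.einsum("of,nfl->nol", wmat, cols, optimize=True)
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, grad):
        n = grad.shape[0]
        g = grad.reshape(n, grad.shape[1], -1)
        wmat = self.w.reshape(self.w.shape[0], -1)
        self.gw[...] = (
            np.einsum("nol,nfl->of", g, self.cols, optimize=True).reshape(self.w.shape)
        )
        dcols = np.einsum("of,nol->nfl", wmat, g, optimize=True)
        return _col2im(dcols, self.x_shape, self.k, self.stride, self.pad, self.ho, self.wo)


class DepthwiseConv2D(Layer):
    """Per-channel 3x3 (or kxk) spatial convolution, no bias."""

    def __init__(self, c: int, k: int, stride: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((c, k, k)) * np.sqrt(2.0 / (k * k))).astype(np.float32)
        self.k, self.stride, self.pad = k, stride, k // 2
        self.gw = np.zeros_like(self.w)
        self.params, self.grads = [self.w], [self.gw]

    def forward(self, x, train):
        self.x_shape = x.shape
        n, c = x.shape[:2]
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        cols = cols.reshape(n, c, self.k * self.k, ho * wo)
        self.cols, self.ho, self.wo = cols, ho, wo
        wmat = self.w.reshape(c, self.k * self.k)
        out = np.einsum("cf,ncfl->ncl", wmat, cols, optimize=True)
        return out.reshape(n, c, ho, wo)

    def backward(self, grad):
        n, c = grad.shape[:2]
        g = grad.reshape(n, c, -1)
        wmat = self.w.reshape(c, self.k * self.k)
        self.gw[...] = np.einsum("ncl,ncfl->cf", g, self.cols, optimize=True).reshape(
            self.w.shape
        )
        dcols = np.einsum("cf,ncl->ncfl", wmat, g, optimize=True)
        dcols = dcols.reshape(n, c * self.k * self.k, -1)
        return _col2im(dcols, self.x_shape, self.k, self.stride, self.pad, self.ho, self.wo)


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.params, self.grads = [self.gamma, self.beta], [self.ggamma, self.gbeta]

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean[None, :, None, None]) * self.inv_std[None, :, None, None]
        self.m = x.shape[0] * x.shape[2] * x.shape[3]
        self.train_mode = train
        return self.gamma[None, :, None, None] * self.xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        axes = (0, 2, 3)
        self.ggamma[...] = np.sum(grad * self.xhat, axis=axes)
        self.gbeta[...] = np.sum(grad, axis=axes)
        if not self.train_mode:
            return grad * (self.gamma * self.inv_std)[None, :, None, None]
        m = self.m
        gx = grad * self.gamma[None, :, None, None]
        dx = (
            gx
            - gx.mean(axis=axes)[None, :, None, None]
            - self.xhat * (gx * self.xhat).mean(axis=axes)[None, :, None, None]
        ) * self.inv_std[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self.shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self.shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self.shape).copy()


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((c_in, c_out)) * np.sqrt(2.0 / c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.params, self.grads = [self.w, self.b], [self.gw, self.gb]

    def forward(self, x, train):
        self.x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw[...] = self.x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-12))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class SGD:
    """Stochastic gradient descent with momentum."""

    def __init__(self, params, grads, lr: float, momentum: float = 0.9):
        self.params, self.grads = params, grads
        self.lr, self.momentum = lr, momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v in zip(self.params, self.grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v
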