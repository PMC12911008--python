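"""Minimal numpy neural-network layers for the fusion classifier.

Implements exactly what the four-channel architecture needs: 1-D convolution
over a single-channel signal, non-overlapping max pooling, dense layers,
ReLU, inverted dropout, Adam, and binary cross-entropy on a single logit.
Everything is float64 and deterministic given the caller's Generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Dense", "Conv1D", "MaxPool1D", "ReLU", "Flatten", "Dropout", "Sequential", "Adam", "bce_with_logits"]


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.n_in = n_in
        scale = np.sqrt(2.0 / n_in)  # He init for ReLU stacks
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        if x.shape[1] != self.n_in:
            raise ValueError(f"feature-length mismatch: expected {self.n_in}, got {x.shape[1]}")
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class Conv1D(Layer):
    """Single-input-channel 1-D convolution: (B, L) -> (B, L_out, F)."""

    def __init__(self, n_filters: int, kernel: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.k, self.stride = kernel, stride
        scale = np.sqrt(2.0 / kernel)
        self.W = rng.normal(0.0, scale, size=(n_filters, kernel))
        self.b = np.zeros(n_filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        if x.shape[1] < self.k:
            raise ValueError(f"input length {x.shape[1]} shorter than kernel {self.k}")
        self._len = x.shape[1]
        win = sliding_window_view(x, self.k, axis=1)[:, :: self.stride, :]
        self._win = win
        return np.einsum("blk,fk->blf", win, self.W) + self.b

    def backward(self, g):
        self.grads[0][...] = np.einsum("blf,blk->fk", g, self._win)
        self.grads[1][...] = g.sum(axis=(0, 1))
        dx = np.zeros((g.shape[0], self._len))
        l_out = g.shape[1]
        starts = self.stride * np.arange(l_out)
        gw = g @ self.W  # (B, L_out, k)
        for t in range(self.k):
            dx[:, starts + t] += gw[:, :, t]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pool over the length axis of (B, L, F)."""

    def __init__(self, pool: int):
        super().__init__()
        self.p = pool

    def forward(self, x, train=False, rng=None):
        b, l, f = x.shape
        n = l // self.p
        self._shape = x.shape
        xr = x[:, : n * self.p].reshape(b, n, self.p, f)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, g):
        b, l, f = self._shape
        n = l // self.p
        dxr = np.zeros((b, n, self.p, f))
        np.put_along_axis(dxr, self._arg[:, :, None, :], g[:, :, None, :], axis=2)
        dx = np.zeros((b, l, f))
        dx[:, : n * self.p] = dxr.reshape(b, n * self.p, f)
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = layers
        for lyr in layers:
            self.params.extend(lyr.params)
            self.grads.extend(lyr.grads)

    def forward(self, x, train=False, rng=None):
        for lyr in self.layers:
            x = lyr.forward(x, train=train, rng=rng)
        return x

    def backward(self, g):
        for lyr in reversed(self.layers):
            g = lyr.backward(g)
        return g


class Adam:
    """Standard adaptive-moment estimation with bias correction."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.ravel()
    # log(1 + e^z) computed stably
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (1.0 / (1.0 + np.exp(-z)) - y) / z.size
    return loss, grad.reshape(logits.shape)
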