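"""Minimal 1-D CNN engine in numpy: layers, Adam, and softmax cross-entropy.

Implements exactly what the spectrum classifier and the DeepLift attribution
need — same-padding 1-D convolutions (im2col + BLAS matmul), truncating max
pooling, leaky ReLU, a dense head — with explicit forward caches so the
attribution stage can walk layers in reverse. Float32 throughout training;
attribution re-runs layers in float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, L) -> (N, L, C*k) windows with zero same-padding (k odd)."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, k, axis=2)            # (N, C, L, k)
    n, c, l, _ = win.shape
    return win.transpose(0, 2, 1, 3).reshape(n, l, c * k)


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """Same-padding 1-D convolution, stride 1, odd kernel."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.normal(0.0, scale, size=(c_out, c_in, k))).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        cols = _im2col(x, self.k)                        # (N, L, C_in*k)
        W2 = self.W.reshape(self.c_out, -1).astype(cols.dtype)
        y = cols @ W2.T + self.b.astype(cols.dtype)      # (N, L, C_out)
        if keep:
            self._cols = cols
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyt = dy.transpose(0, 2, 1)                      # (N, L, C_out)
        n, l, _ = dyt.shape
        flat_dy = dyt.reshape(-1, self.c_out)
        flat_cols = self._cols.reshape(-1, self.c_in * self.k)
        self.dW = (flat_dy.T @ flat_cols).reshape(self.W.shape).astype(self.W.dtype)
        self.db = flat_dy.sum(axis=0).astype(self.b.dtype)
        self._cols = None
        return self.input_backward(dy)

    def input_backward(self, dy: np.ndarray) -> np.ndarray:
        """Gradient/multiplier wrt the layer input: correlation of ``dy``
        with the flipped kernels (valid for any linear multiplier)."""
        Wflip = self.W[:, :, ::-1].transpose(1, 0, 2)    # (C_in, C_out, k)
        cols = _im2col(dy, self.k)                       # (N, L, C_out*k)
        W2 = Wflip.reshape(self.c_in, -1).astype(cols.dtype)
        dx = cols @ W2.T                                 # (N, L, C_in)
        return np.ascontiguousarray(dx.transpose(0, 2, 1))

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        if keep:
            self._x = x
        return np.where(x > 0, x, x * np.asarray(self.slope, dtype=x.dtype))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = np.where(self._x > 0, 1.0, self.slope).astype(dy.dtype)
        self._x = None
        return dy * d

    def derivative(self, x: np.ndarray) -> np.ndarray:
        return np.where(x > 0, 1.0, self.slope)


class MaxPool1d(Layer):
    """Non-overlapping max pooling of width p; a trailing remainder of the
    sequence (length % p) is dropped."""

    def __init__(self, p: int):
        self.p = p
        self._argmax: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        n, c, l = x.shape
        lp = l // self.p
        if lp < 1:
            raise ValueError(f"pooling width {self.p} collapses length {l} to 0")
        xr = x[:, :, :lp * self.p].reshape(n, c, lp, self.p)
        if keep:
            self._argmax = xr.argmax(axis=3)
            self._in_len = l
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, lp = dy.shape
        dx = np.zeros((n, c, lp, self.p), dtype=dy.dtype)
        np.put_along_axis(dx, self._argmax[..., None], dy[..., None], axis=3)
        dx = dx.reshape(n, c, lp * self.p)
        if self._in_len > lp * self.p:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, self._in_len - lp * self.p)))
        self._argmax = None
        return dx


class Flatten(Layer):
    def __init__(self):
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        if keep:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_out, n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        if keep:
            self._x = x
        return x @ self.W.T.astype(x.dtype) + self.b.astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = (dy.T @ self._x).astype(self.W.dtype)
        self.db = dy.sum(axis=0).astype(self.b.dtype)
        self._x = None
        return dy @ self.W.astype(dy.dtype)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, keep=keep)
        return x

    def forward_trace(self, x: np.ndarray) -> list[np.ndarray]:
        """Return [input, after layer 0, after layer 1, ...] without caching."""
        trace = [x]
        for layer in self.layers:
            # pooling needs its argmax later; recomputed by the attribution walk
            x = layer.forward(x, keep=False)
            trace.append(x)
        return trace

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dz = p
    dz[np.arange(n), y] -= 1.0
    return loss, (dz / n).astype(logits.dtype)


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
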