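"""Minimal numpy neural-network core: 3D convolutions, pooling, linear
layers, dropout, and Adam, with explicit forward/backward passes.

Shapes: convolutional tensors are single-sample ``(C, D, H, W)``; dense
layers operate on batches ``(n, d)``.  3x3x3 same-padding convolution is
computed as 27 shifted channel-mixing GEMMs, which keeps peak memory at a few
copies of the activation map and routes the arithmetic through BLAS.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = [
    "Conv3d",
    "Conv1x1",
    "Linear",
    "relu",
    "relu_backward",
    "maxpool2",
    "maxpool2_backward",
    "upsample2",
    "upsample2_backward",
    "adaptive_avg_pool",
    "Dropout",
    "Adam",
    "he_init",
    "params_hash",
]


def he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d:
    """3x3x3 convolution, stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.c_in, self.c_out = c_in, c_out
        self.W = he_init(rng, (c_out, c_in, 3, 3, 3), fan_in=c_in * 27, dtype=dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, D, H, W = x.shape
        assert c == self.c_in, (c, self.c_in)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        out = np.zeros((self.c_out, D * H * W), dtype=x.dtype)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = xp[:, i : i + D, j : j + H, k : k + W].reshape(c, -1)
                    out += self.W[:, :, i, j, k] @ xs
        out += self.b[:, None]
        self._xp = xp
        return out.reshape(self.c_out, D, H, W)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_out, D, H, W = dy.shape
        xp = self._xp
        dy2 = dy.reshape(c_out, -1)
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = xp[:, i : i + D, j : j + H, k : k + W].reshape(self.c_in, -1)
                    self.dW[:, :, i, j, k] += dy2 @ xs.T
                    dxp[:, i : i + D, j : j + H, k : k + W] += (
                        self.W[:, :, i, j, k].T @ dy2
                    ).reshape(self.c_in, D, H, W)
        self.db += dy2.sum(axis=1)
        return dxp[:, 1:-1, 1:-1, 1:-1]

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Conv1x1:
    """Pointwise channel-mixing convolution (the segmentation head)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = he_init(rng, (c_out, c_in), fan_in=c_in, dtype=dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, D, H, W = x.shape
        self._x = x
        out = self.W @ x.reshape(c, -1) + self.b[:, None]
        return out.reshape(-1, D, H, W)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_out, D, H, W = dy.shape
        dy2 = dy.reshape(c_out, -1)
        x2 = self._x.reshape(self._x.shape[0], -1)
        self.dW += dy2 @ x2.T
        self.db += dy2.sum(axis=1)
        return (self.W.T @ dy2).reshape(self._x.shape)

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float64):
        self.W = he_init(rng, (d_out, d_in), fan_in=d_in, dtype=dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += dy.T @ self._x
        self.db += dy.sum(axis=0)
        return dy @ self.W

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def relu_backward(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return dy * (y > 0)


def maxpool2(x: np.ndarray):
    """Factor-2 max pooling over the spatial axes; dims must be even."""
    c, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"spatial dims must be even for 2x pooling, got {(D, H, W)}")
    xr = x.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2)
    xw = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, D // 2, H // 2, W // 2, 8)
    idx = xw.argmax(axis=-1)
    out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache) -> np.ndarray:
    idx, shape = cache
    c, D, H, W = shape
    dxw = np.zeros((c, D // 2, H // 2, W // 2, 8), dtype=dy.dtype)
    np.put_along_axis(dxw, idx[..., None], dy[..., None], axis=-1)
    dxr = dxw.reshape(c, D // 2, H // 2, W // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
    return dxr.reshape(c, D, H, W)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, D, H, W = dy.shape
    return dy.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2).sum(axis=(2, 4, 6))


def adaptive_avg_pool(x: np.ndarray, grid) -> np.ndarray:
    """Average-pool (C, D, H, W) onto a (g0, g1, g2) grid with near-equal bins."""
    c = x.shape[0]
    g = tuple(int(v) for v in grid)
    for ax in range(3):
        if g[ax] > x.shape[ax + 1]:
            raise ValueError(
                f"pooled_grid {g} exceeds bottleneck spatial size {x.shape[1:]}"
            )
    out = np.empty((c, g[0], g[1], g[2]), dtype=np.float64)
    bounds = [np.linspace(0, x.shape[ax + 1], g[ax] + 1).astype(int) for ax in range(3)]
    for a in range(g[0]):
        for b in range(g[1]):
            for d in range(g[2]):
                block = x[
                    :,
                    bounds[0][a] : bounds[0][a + 1],
                    bounds[1][b] : bounds[1][b + 1],
                    bounds[2][d] : bounds[2][d + 1],
                ]
                out[:, a, b, d] = block.mean(axis=(1, 2, 3))
    return out


class Dropout:
    def __init__(self, p: float):
        self.p = float(p)
        self._mask = None

    def forward(self, x: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        if rng is None or self.p <= 0:  # eval mode
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Adam:
    def __init__(self, param_pairs, lr: float, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.pairs = list(param_pairs)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]

    def zero_grad(self):
        for _, g in self.pairs:
            g[...] = 0.0

    def step(self):
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (p, g) in enumerate(self.pairs):
            geff = g + self.weight_decay * p if self.weight_decay else g
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * geff
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * geff * geff
            p -= (self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)).astype(p.dtype)


def params_hash(param_pairs) -> str:
    """SHA-256 over the raw bytes of all parameters (freeze verification)."""
    h = hashlib.sha256()
    for p, _ in param_pairs:
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()
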