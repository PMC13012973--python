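"""Minimal NumPy neural-network core for the segmentation and regression models.

Implements just the pieces the pipeline needs: 3x3/1x1 convolutions (im2col +
BLAS), batch normalization with three statistic modes, ReLU, 2x2 max-pool,
nearest-neighbour upsampling, linear heads, Adam, and L1 / binary-cross-entropy
losses.  Everything is float32 and fully deterministic given a seed and a fixed
thread count.

Normalization modes
-------------------
``train``  batch statistics; running mean/var buffers are updated.
``eval``   stored running statistics (the usual inference mode).
``adapt``  statistics recomputed from the current input only, with NO buffer or
           parameter updates — the test-time adaptation used to survive domain
           shift: when inference images have different global intensity
           statistics than the training domain, stored running statistics
           mis-normalize the features, while per-input statistics track each
           image.

Convolutions pad with edge replication, so a constant input maps to a constant
per-channel output.  Together with a Conv->BN head this makes thresholded
network outputs exactly invariant to positive affine intensity transforms of
the input when BN runs in ``adapt`` mode (up to floating point).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidInputError

F32 = np.float32


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: parameters, gradients and persistent (non-trained) buffers."""

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int) -> tuple[np.ndarray, tuple[int, int]]:
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    n, c, h, w = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * k * k)
    return cols, (h, w)


class Conv2d(Layer):
    """k=1 or k=3 convolution, stride 1; k=3 uses edge-replicate padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise InvalidInputError("Conv2d supports k in {1, 3}")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        self.weight = (rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.bias = np.zeros(cout, dtype=F32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cache: tuple | None = None

    def parameters(self):
        return [self.weight, self.bias]

    def gradients(self):
        return [self.dweight, self.dbias]

    def forward(self, x, mode):
        k = self.k
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge") if k == 3 else x
        cols, (h, w) = _im2col(xp, k)
        wm = self.weight.reshape(self.cout, -1)
        y = cols @ wm.T + self.bias
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(y.transpose(0, 2, 1)).reshape(x.shape[0], self.cout, h, w)

    def backward(self, dy):
        cols, xshape = self._cache
        n, _, h, w = dy.shape
        k, cin = self.k, self.cin
        dyc = np.ascontiguousarray(dy.reshape(n, self.cout, h * w).transpose(0, 2, 1))
        flat_dy = dyc.reshape(-1, self.cout)
        flat_cols = cols.reshape(-1, cin * k * k)
        self.dweight[...] = (flat_dy.T @ flat_cols).reshape(self.weight.shape)
        self.dbias[...] = flat_dy.sum(axis=0)
        dcols = dyc @ self.weight.reshape(self.cout, -1)  # (N,HW,C*k*k)
        if k == 1:
            return np.ascontiguousarray(
                dcols.reshape(n, h, w, cin).transpose(0, 3, 1, 2))
        dcols = dcols.reshape(n, h, w, cin, k, k)
        dxp = np.zeros((n, cin, h + 2, w + 2), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        # fold gradients of replicated border pixels back onto the edges
        dx = dxp[:, :, 1:-1, 1:-1].copy()
        dx[:, :, 0, :] += dxp[:, :, 0, 1:-1]
        dx[:, :, -1, :] += dxp[:, :, -1, 1:-1]
        dx[:, :, :, 0] += dxp[:, :, 1:-1, 0]
        dx[:, :, :, -1] += dxp[:, :, 1:-1, -1]
        dx[:, :, 0, 0] += dxp[:, :, 0, 0]
        dx[:, :, 0, -1] += dxp[:, :, 0, -1]
        dx[:, :, -1, 0] += dxp[:, :, -1, 0]
        dx[:, :, -1, -1] += dxp[:, :, -1, -1]
        return dx


class BatchNorm2d(Layer):
    """Channel normalization with per-sample (instance) statistics.

    ``train``/``adapt`` normalize each sample by its own per-channel spatial
    mean/variance, so inference with per-input statistics (``adapt``) sees
    exactly the normalization used during training; ``train`` additionally
    maintains running buffers (batch-averaged per-sample statistics) that the
    ``eval`` mode uses — the stored-statistics path that breaks under domain
    shift and that test-time adaptation bypasses.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.dgamma, self.dbeta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, mode):
        if mode in ("train", "adapt"):
            mu = x.mean(axis=(2, 3), keepdims=True)       # (N,C,1,1)
            var = x.var(axis=(2, 3), keepdims=True)
            if mode == "train":
                m = self.momentum
                self.running_mean[...] = ((1 - m) * self.running_mean
                                          + m * mu.mean(axis=0)[:, 0, 0])
                self.running_var[...] = ((1 - m) * self.running_var
                                         + m * var.mean(axis=0)[:, 0, 0])
        else:
            mu = self.running_mean[None, :, None, None]
            var = self.running_var[None, :, None, None]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, mode)
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None]).astype(F32)

    def backward(self, dy):
        xhat, inv, mode = self._cache
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        if mode == "eval":
            return (dy * g * inv).astype(F32)
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True))
        return (dx * inv).astype(F32)


class ReLU(Layer):
    def forward(self, x, mode):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(F32)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x, mode):
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
        self._arg = blocks.argmax(axis=-1)
        self._shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._shape
        dblocks = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(dblocks, self._arg[..., None], dy[..., None], axis=-1)
        dx = dblocks.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, mode):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x, mode):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).astype(F32)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.weight = (rng.standard_normal((cout, cin)) * np.sqrt(1.0 / cin)).astype(F32)
        self.bias = np.zeros(cout, dtype=F32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def parameters(self):
        return [self.weight, self.bias]

    def gradients(self):
        return [self.dweight, self.dbias]

    def forward(self, x, mode):
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, dy):
        self.dweight[...] = dy.T @ self._x
        self.dbias[...] = dy.sum(axis=0)
        return (dy @ self.weight).astype(F32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def gradients(self):
        return [g for l in self.layers for g in l.gradients()]

    def buffers(self):
        out = {}
        for i, l in enumerate(self.layers):
            for k, v in l.buffers().items():
                out[f"{i}.{k}"] = v
        return out

    def forward(self, x, mode):
        for l in self.layers:
            x = l.forward(x, mode)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# optimiser and losses
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Iterable[np.ndarray], grads: Iterable[np.ndarray],
                 lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.grads = list(grads)
        if len(self.params) != len(self.grads):
            raise InvalidInputError("params and grads must align")
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    pos_weight: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits).

    ``pos_weight`` (broadcastable to the logits, e.g. per-channel) up-weights
    positive targets — the usual counter to foreground/background imbalance
    that otherwise lets a sparse channel collapse to all-negative.
    """
    z, t = logits.astype(np.float64), targets
    ce = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    if pos_weight is None:
        w = 1.0
    else:
        w = np.where(t > 0.5, pos_weight, 1.0)
    loss = np.mean(w * ce)
    grad = (w * (p - t) / z.size).astype(F32)
    return float(loss), grad


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    d = pred - target
    return float(np.mean(np.abs(d))), (np.sign(d) / d.size).astype(F32)


def l2_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    d = pred - target
    return float(np.mean(d * d)), (2.0 * d / d.size).astype(F32)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def state_dict(model: Layer) -> dict[str, np.ndarray]:
    out = {f"p{i}": p for i, p in enumerate(model.parameters())}
    for k, v in model.buffers().items():
        out[f"b:{k}"] = v
    return out

def load_state_dict(model: Layer, state: dict[str, np.ndarray]) -> None:
    for i, p in enumerate(model.parameters()):
        p[...] = state[f"p{i}"]
    for k, v in model.buffers().items():
        v[...] = state[f"b:{k}"]
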