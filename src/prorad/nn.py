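"""Minimal NumPy neural-network layers for the compact RSM classifier.

Implements exactly what the multi-label deviation classifier needs — 3x3
convolutions (im2col + BLAS matmul), batch normalisation, ReLU, 2x2 max
pooling, dropout, global average pooling, dense layers, the structured
category-subset head, sigmoid/binary-cross-entropy with logits, and an
AdamW optimiser with decoupled weight decay.  Everything is deterministic
given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "AdamW",
    "BatchNorm2d",
    "ComposeClasses",
    "Conv2d",
    "Dense",
    "Dropout",
    "Flatten",
    "GlobalAvgPool",
    "MaxPool2d",
    "ReLU",
    "Sequential",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all elements; returns (loss, dloss/dlogits).

    ``pos_weight > 1`` up-weights positive targets, countering the 1-in-28
    positive/negative imbalance of one-hot multi-label rows.
    """
    # per-element softplus terms computed stably
    softplus = np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    w = 1.0 + (pos_weight - 1.0) * targets
    loss = np.mean(w * softplus)
    grad = w * (sigmoid(logits) - targets) / logits.size
    return float(loss), grad


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]
    buffer_names: tuple[str, ...] = ()

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 same-padding convolution on NCHW tensors via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, ksize: int = 3):
        super().__init__()
        k = ksize
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU nets
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * k * k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n, h*w, c*k*k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, -1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        cols = self._im2col(x)
        if train:
            self._cols = cols
        n, c, h, w = x.shape
        out = cols @ self.w.T + self.b
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c_in, h, w = self._shape
        gf = np.ascontiguousarray(g.reshape(n, -1, h * w).transpose(0, 2, 1))  # (n, hw, c_out)
        gflat = gf.reshape(-1, gf.shape[2])
        self.grads[0][...] = gflat.T @ self._cols.reshape(-1, self._cols.shape[2])
        self.grads[1][...] = gflat.sum(axis=0)
        dcols = gf @ self.w  # (n, hw, c_in*k*k)
        # col2im: scatter-add back into the padded input
        p = self.k // 2
        dxp = np.zeros((n, c_in, h + 2 * p, w + 2 * p), dtype=g.dtype)
        dcols = dcols.reshape(n, h, w, c_in, self.k, self.k).transpose(0, 3, 1, 2, 4, 5)
        for ky in range(self.k):
            for kx in range(self.k):
                dxp[:, :, ky : ky + h, kx : kx + w] += dcols[:, :, :, :, ky, kx]
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalisation on NCHW tensors (running stats at eval)."""

    buffer_names = ("running_mean", "running_var")

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        self._n = x.shape[0] * x.shape[2] * x.shape[3]
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        self.grads[0][...] = np.sum(g * self._xhat, axis=axes)
        self.grads[1][...] = np.sum(g, axis=axes)
        gx = g * self.gamma[None, :, None, None]
        if not self._train:
            return gx / self._std
        n = self._n
        return (
            gx - gx.mean(axis=axes, keepdims=True)
            - self._xhat * np.mean(gx * self._xhat, axis=axes, keepdims=True)
        ) / self._std


class Dropout(Layer):
    """Inverted dropout; identity at eval.  Seeded for determinism."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class ComposeClasses(Layer):
    """Structured head: category logits -> class-subset logits.

    Given 7 independent category logits ``z`` and a fixed membership matrix
    ``M`` (n_classes x 7, rows are the category subsets defining each
    class), the probability of class ``S`` under independent categories is
    ``p_S = prod_{m in S} sigma(z_m) * prod_{m not in S} (1 - sigma(z_m))``
    (the empty subset being the no-relevant-deviation class).  The layer
    emits ``logit(p_S)``, so downstream sigmoid outputs are exactly the
    subset probabilities.  Baking the subset algebra into the head means
    only the 7 category detectors have to generalise.
    """

    def __init__(self, membership: np.ndarray, eps: float = 1e-7):
        super().__init__()
        self.m = membership.astype(np.float32)  # (n_classes, n_cat)
        self.eps = eps

    def forward(self, z: np.ndarray, train: bool) -> np.ndarray:
        s = sigmoid(z)
        s = np.clip(s, self.eps, 1.0 - self.eps)
        self._s = s
        log_p = np.log(s)
        log_q = np.log(1.0 - s)
        a = log_p @ self.m.T + log_q @ (1.0 - self.m).T  # log p_S
        a = np.minimum(a, -self.eps)
        self._a = a
        return a - np.log1p(-np.exp(a))

    def backward(self, g: np.ndarray) -> np.ndarray:
        da = g / (1.0 - np.exp(self._a))  # dlogit/da = 1/(1 - e^a)
        pos = da @ self.m  # (n, n_cat)
        neg = da @ (1.0 - self.m)
        return pos * (1.0 - self._s) - neg * self._s


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling (inputs must have even spatial dims)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        gr = np.broadcast_to(g[:, :, :, None, :, None], self._mask.shape)
        return (gr * self._mask).reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def get_weights(self) -> list[np.ndarray]:
        """Full network state: parameters plus layer buffers (e.g. BN stats)."""
        out = [p.copy() for p in self.params]
        for l in self.layers:
            out.extend(getattr(l, name).copy() for name in l.buffer_names)
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, w in zip(self.params, weights[:n]):
            p[...] = w
        i = n
        for l in self.layers:
            for name in l.buffer_names:
                setattr(l, name, weights[i].copy())
                i += 1


class AdamW:
    """Adam with decoupled weight decay (weight decay skips biases/1-D params)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            if p.ndim > 1:  # decoupled decay on weight matrices only
                p *= 1.0 - self.lr * self.wd
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
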