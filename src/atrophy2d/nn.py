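"""Minimal NumPy neural-network core used by the segmentation and MLP stages.

Implements exactly the pieces the pipeline needs — 2D convolution, batch
normalization, max-pooling / nearest upsampling, dense layers, dropout, ReLU,
Adam with L2 weight penalty, and sparse softmax cross-entropy — with explicit
forward/backward passes. Gradients are finite-difference checked in the test
suite. Everything is deterministic given a `numpy.random.Generator`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "BatchNorm1d",
    "Dense",
    "ReLU",
    "Dropout",
    "MaxPool2d",
    "UpsampleNearest2d",
    "Adam",
    "softmax_cross_entropy",
    "sigmoid",
    "binary_cross_entropy",
    "MLP",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        value = np.asarray(value)
        if not np.issubdtype(value.dtype, np.floating):
            value = value.astype(np.float64)
        self.value = value
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """Same-padded 2D convolution in NHWC float32, He-initialised.

    Implemented as k*k shifted GEMMs (one per kernel offset) rather than
    im2col, which keeps memory traffic low on a single CPU.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError(f"kernel size must be odd, got {k}")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.normal(0.0, scale,
                                  size=(k * k, c_in, c_out)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._offsets = [(i, j) for i in range(k) for j in range(k)]

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n, h, w, k * k * c), dtype=x.dtype)
        for idx, (di, dj) in enumerate(self._offsets):
            cols[..., idx * c : (idx + 1) * c] = xp[:, di : di + h, dj : dj + w, :]
        cols = cols.reshape(n * h * w, k * k * c)
        self._cols, self._xshape = cols, x.shape
        wflat = self.W.value.reshape(k * k * c, self.c_out)
        out = cols @ wflat + self.b.value
        return out.reshape(n, h, w, self.c_out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        k, p = self.k, self.k // 2
        flat_g = np.ascontiguousarray(g).reshape(-1, self.c_out)
        self.b.grad += flat_g.sum(axis=0)
        self.W.grad += (self._cols.T @ flat_g).reshape(self.W.value.shape)
        wflat = self.W.value.reshape(k * k * c, self.c_out)
        dcols = (flat_g @ wflat.T).reshape(n, h, w, k * k * c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=self._cols.dtype)
        for idx, (di, dj) in enumerate(self._offsets):
            dxp[:, di : di + h, dj : dj + w, :] += \
                dcols[..., idx * c : (idx + 1) * c]
        return dxp[:, p : p + h, p : p + w, :]


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W), NHWC layout."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    _axes = (0, 1, 2)

    def _shape(self, v: np.ndarray) -> np.ndarray:
        return v.reshape(1, 1, 1, -1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - self._shape(mean)) / self._shape(std)
        self._xhat, self._std, self._train = xhat, std, train
        return self._shape(self.gamma.value) * xhat + self._shape(self.beta.value)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.gamma.grad += (g * xhat).sum(axis=self._axes)
        self.beta.grad += g.sum(axis=self._axes)
        gxhat = g * self._shape(self.gamma.value)
        if not self._train:
            return gxhat / self._shape(std)
        m = np.prod([xhat.shape[a] for a in self._axes])
        term = gxhat - gxhat.mean(axis=self._axes, keepdims=True) \
            - xhat * (gxhat * xhat).sum(axis=self._axes, keepdims=True) / m
        return term / self._shape(std)


class BatchNorm1d(BatchNorm2d):
    _axes = (0,)

    def _shape(self, v: np.ndarray) -> np.ndarray:
        return v.reshape(1, -1)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, NHWC; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = np.ascontiguousarray(r).reshape(n, h // 2, w // 2, c, 4)
        self._argmax = r.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(r, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        out = np.zeros((n, h // 2, w // 2, c, 4), dtype=g.dtype)
        np.put_along_axis(out, self._argmax[..., None], g[..., None], axis=-1)
        out = out.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(out).reshape(n, h, w, c)


class UpsampleNearest2d(Layer):
    """Nearest-neighbour 2x upsampling, NHWC."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h2, w2, c = g.shape
        return g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Adam with a classic L2 penalty folded into the gradient."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad + self.wd * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Sparse softmax cross-entropy.

    logits: (..., K) scores over K classes; labels: integer array matching the
    leading shape. Returns (mean loss, gradient w.r.t. logits).
    """
    flat = logits.reshape(-1, logits.shape[-1])
    lab = labels.reshape(-1).astype(np.int64)
    shifted = flat - flat.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    n = flat.shape[0]
    loss = -logp[np.arange(n), lab].mean()
    grad = np.exp(logp)
    grad[np.arange(n), lab] -= 1.0
    grad /= n
    return loss, grad.reshape(logits.shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binary_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Sigmoid BCE on raw logits. Returns (mean loss, grad w.r.t. logits)."""
    z = logits.reshape(-1)
    y = y.reshape(-1).astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.reshape(logits.shape)


@dataclass
class MLP:
    """Two-hidden-layer perceptron with dropout, trained by Adam.

    task: "regression" (linear output, MSE on standardized targets) or
    "binary" (sigmoid output in [0, 1], BCE loss). Inputs are standardized
    with train-set mean/SD stored on the model; regression targets likewise.
    """

    hidden1: int = 32
    hidden2: int = 16
    dropout: float = 0.3
    lr: float = 3e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    epochs: int = 300
    patience: int = 20
    min_delta: float = 1e-6
    task: str = "regression"
    seed: int = 0
    # fitted state
    layers: list = field(default_factory=list, repr=False)
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0
    loss_history: list = field(default_factory=list, repr=False)

    @property
    def fitted(self) -> bool:
        return bool(self.layers)

    def _build(self, d_in: int, rng: np.random.Generator) -> None:
        self.layers = [
            Dense(d_in, self.hidden1, rng), ReLU(), Dropout(self.dropout, rng),
            Dense(self.hidden1, self.hidden2, rng), ReLU(), Dropout(self.dropout, rng),
            Dense(self.hidden2, 1, rng),
        ]

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def _backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLP":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).reshape(-1)
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in training data")
        rng = np.random.default_rng(self.seed)
        self.x_mean = X.mean(axis=0)
        self.x_sd = X.std(axis=0)
        self.x_sd[self.x_sd == 0] = 1.0
        Xs = (X - self.x_mean) / self.x_sd
        if self.task == "regression":
            self.y_mean = float(y.mean())
            self.y_sd = float(y.std()) or 1.0
            yt = (y - self.y_mean) / self.y_sd
        else:
            yt = y
        self._build(X.shape[1], rng)
        opt = Adam(self.params(), lr=self.lr, weight_decay=self.weight_decay)
        n = X.shape[0]
        best, wait = np.inf, 0
        self.loss_history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                out = self._forward(Xs[idx], train=True)
                if self.task == "regression":
                    diff = out.reshape(-1) - yt[idx]
                    loss = float(np.mean(diff**2))
                    grad = (2.0 * diff / diff.size).reshape(out.shape)
                else:
                    loss, grad = binary_cross_entropy(out, yt[idx])
                opt.zero_grad()
                self._backward(grad)
                opt.step()
                epoch_loss += loss * len(idx)
            epoch_loss /= n
            self.loss_history.append(epoch_loss)
            if epoch_loss < best - self.min_delta:
                best, wait = epoch_loss, 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not trained")
        X = np.asarray(X, dtype=np.float64)
        Xs = (X - self.x_mean) / self.x_sd
        out = self._forward(Xs, train=False).reshape(-1)
        if self.task == "regression":
            return out * self.y_sd + self.y_mean
        return sigmoid(out)

    # --- serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        d = {f"p{i}": p.value for i, p in enumerate(self.params())}
        d["x_mean"], d["x_sd"] = self.x_mean, self.x_sd
        d["y_scale"] = np.array([self.y_mean, self.y_sd])
        return d

    def config_json(self) -> str:
        keys = ("hidden1", "hidden2", "dropout", "lr", "weight_decay",
                "batch_size", "epochs", "task", "seed")
        return json.dumps({k: getattr(self, k) for k in keys}, sort_keys=True)
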