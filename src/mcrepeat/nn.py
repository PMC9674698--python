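"""Minimal CNN engine: layers, backprop, and the Adam optimizer.

A compact, fully seeded convolutional stack sufficient for desk-scale
severity classifiers on small grayscale images. Tensors follow the
(batch, channels, height, width) layout. Each layer caches what its
backward pass needs; ``Sequential`` chains them and exposes the parameter
list for the optimizer.

Stochasticity is confined to ``ChannelDropout``: whole feature channels
are zeroed independently per forward pass (spatial dropout), with inverted
scaling by 1/(1-rate) so activations keep their expectation. The same
layer serves training and test-time Monte Carlo sampling; every other
layer is deterministic, so a dropout-free network is bitwise repeatable.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "ChannelDropout",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "CoralHead",
    "Sequential",
    "Adam",
    "ReduceLROnPlateau",
]


class Layer:
    """Base layer. Subclasses implement forward/backward and list params."""

    def forward(self, x: np.ndarray, *, stochastic: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """3x3 same-padding convolution implemented via im2col."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, rng: np.random.Generator | None = None):
        if ksize % 2 != 1:
            raise ValueError("ksize must be odd (same padding)")
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        self.pad = ksize // 2
        fan_in = c_in * ksize * ksize
        self.W = _he_init(rng, (c_out, fan_in), fan_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        p, k = self.pad, self.ksize
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
        B, C, H, W = x.shape
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)

    def forward(self, x, *, stochastic=False, rng=None):
        B, C, H, W = x.shape
        cols = self._im2col(x)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.W.T + self.b  # (B, H*W, c_out)
        return out.transpose(0, 2, 1).reshape(B, self.c_out, H, W)

    def backward(self, grad):
        B, C, H, W = self._xshape
        k, p = self.ksize, self.pad
        g = grad.reshape(B, self.c_out, H * W).transpose(0, 2, 1)  # (B,H*W,c_out)
        ckk = self._cols.shape[-1]
        self.dW[...] = g.reshape(-1, self.c_out).T @ self._cols.reshape(-1, ckk)
        self.db[...] = g.sum(axis=(0, 1))
        dcols = g @ self.W  # (B, H*W, C*k*k)
        d = dcols.reshape(B, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += d[:, :, :, :, i, j]
        return dxp[:, :, p : p + H, p : p + W]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, *, stochastic=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling (input H, W must be even)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, *, stochastic=False, rng=None):
        s = self.size
        B, C, H, W = x.shape
        if H % s or W % s:
            raise ValueError(f"spatial dims {(H, W)} not divisible by pool size {s}")
        win = x.reshape(B, C, H // s, s, W // s, s).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(B, C, H // s, W // s, s * s)
        self._argmax = flat.argmax(axis=-1)
        self._inshape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad):
        s = self.size
        B, C, H, W = self._inshape
        flat = np.zeros((B, C, H // s, W // s, s * s), dtype=grad.dtype)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        win = flat.reshape(B, C, H // s, W // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        return win.reshape(B, C, H, W)


class ChannelDropout(Layer):
    """Spatial dropout: zero whole feature channels with probability ``rate``.

    Active only when the forward pass is stochastic (training, or test-time
    MC sampling); a deterministic pass is the identity. Uses inverted
    scaling so the expected activation is unchanged.
    """

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | float = 1.0
        #: when set, masks come from this dedicated stream instead of the
        #: pass-level rng (one stream per layer keeps the first n rows of a
        #: tiled MC batch identical across batch sizes)
        self.mask_rng: np.random.Generator | None = None

    def forward(self, x, *, stochastic=False, rng=None):
        if not stochastic or self.rate == 0.0:
            self._mask = 1.0
            return x
        gen = self.mask_rng if self.mask_rng is not None else rng
        if gen is None:
            raise ValueError("stochastic dropout pass requires an rng")
        keep = gen.random((x.shape[0], x.shape[1]) + (1,) * (x.ndim - 2)) >= self.rate
        self._mask = (keep / (1.0 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, *, stochastic=False, rng=None):
        self._inshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._inshape)


class GlobalAvgPool(Layer):
    def forward(self, x, *, stochastic=False, rng=None):
        self._inshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._inshape
        return np.broadcast_to(grad[:, :, None, None], self._inshape) / (H * W)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, *, stochastic=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class CoralHead(Layer):
    """Rank-consistent ordinal head: one shared weight vector, k-1 biases.

    Logit for threshold task j is ``x . w + b_j``. Because the weight
    vector is shared, the sigmoid outputs are ordered by the biases alone,
    which (after training drives the biases monotone) yields the CORAL
    rank-monotonicity property.
    """

    def __init__(self, n_in: int, k: int, rng: np.random.Generator | None = None):
        if k < 3:
            raise ValueError("ordinal head requires k >= 3")
        rng = rng or np.random.default_rng(0)
        self.k = k
        self.w = _he_init(rng, (n_in, 1), n_in)
        # bias init descending in j encourages q_1 >= q_2 >= ... from the start
        self.b = np.linspace(0.5, -0.5, k - 1, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, *, stochastic=False, rng=None):
        self._x = x
        return x @ self.w + self.b  # (B, k-1)

    def backward(self, grad):
        self.dw[...] = (self._x.T @ grad).sum(axis=1, keepdims=True)
        self.db[...] = grad.sum(axis=0)
        return grad.sum(axis=1, keepdims=True) @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Sequential:
    """Chain of layers with a shared stochastic/deterministic switch."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, *, stochastic: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, stochastic=stochastic, rng=rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def dropout_layers(self) -> list[ChannelDropout]:
        return [l for l in self.layers if isinstance(l, ChannelDropout)]

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p[...] = s


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored loss."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 10,
                 min_delta: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> None:
        if loss < self.best - self.min_delta:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr *= self.factor
                self.bad_epochs = 0
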