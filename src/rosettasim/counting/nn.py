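"""Minimal feed-forward CNN building blocks with explicit backpropagation.

Layers operate on NHWC float32 arrays.  This is a small, deterministic,
CPU-only implementation: convolution is im2col + matmul, pooling stores its
argmax for the backward pass, and the optimizer is Adam (or plain SGD).
It is sized for the leaf-count regression networks in this package, not for
general deep learning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "MaxPool2D", "Tanh", "Flatten", "Dense", "Sequential", "Adam", "SGD"]


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list:
        return []

    @property
    def grads(self) -> list:
        return []

    def out_shape(self, shape: tuple) -> tuple:
        return shape


class Conv2D(Layer):
    """Same-padded k x k convolution with stride 1 and bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = rng.uniform(-limit, limit, size=(fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: Optional[np.ndarray] = None
        self._xshape: Optional[tuple] = None

    @property
    def params(self) -> list:
        return [self.w, self.b]

    @property
    def grads(self) -> list:
        return [self.dw, self.db]

    @property
    def decay_mask(self) -> list:
        return [True, False]  # no decay on biases

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))  # N,H,W,C,k,k
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, self.k * self.k * c)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = cols @ self.w + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = grad.shape
        gflat = grad.reshape(-1, self.c_out)
        self.dw[...] = self._cols.T @ gflat
        self.db[...] = gflat.sum(axis=0)
        dcols = (gflat @ self.w.T).reshape(n, h, w, self.k, self.k, self.c_in)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, p:p + h, p:p + w, :]

    def out_shape(self, shape: tuple) -> tuple:
        h, w, _ = shape
        return (h, w, self.c_out)


class MaxPool2D(Layer):
    """k x k max pooling (default 3x3, stride 2)."""

    def __init__(self, kernel: int = 3, stride: int = 2):
        self.k = kernel
        self.s = stride
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        win = sliding_window_view(x, (self.k, self.k), axis=(1, 2))[:, ::self.s, ::self.s]
        n_, ho, wo, c_, _, _ = win.shape
        flat = win.reshape(n_, ho, wo, c_, self.k * self.k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, arg)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (xshape, arg) = self._cache
        n, h, w, c = xshape
        _, ho, wo, _ = grad.shape
        dx = np.zeros(xshape, dtype=np.float32)
        di, dj = np.divmod(arg, self.k)
        ni, oi, oj, ci = np.indices(arg.shape, sparse=False)
        rows = oi * self.s + di
        cols = oj * self.s + dj
        np.add.at(dx, (ni, rows, cols, ci), grad)
        self._cache = None
        return dx

    def out_shape(self, shape: tuple) -> tuple:
        h, w, c = shape
        return ((h - self.k) // self.s + 1, (w - self.k) // self.s + 1, c)


class Tanh(Layer):
    def __init__(self):
        self._out = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.tanh(x)
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = self._out
        self._out = None
        return grad * (1.0 - out * out)


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def out_shape(self, shape: tuple) -> tuple:
        return (int(np.prod(shape)),)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.w = rng.uniform(-limit, limit, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self) -> list:
        return [self.w, self.b]

    @property
    def grads(self) -> list:
        return [self.dw, self.db]

    @property
    def decay_mask(self) -> list:
        return [True, False]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        dx = grad @ self.w.T
        self._x = None
        return dx

    def out_shape(self, shape: tuple) -> tuple:
        return (self.w.shape[1],)


@dataclass
class Sequential:
    layers: list

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list:
        out = []
        for layer in self.layers:
            ps, gs = layer.params, layer.grads
            masks = getattr(layer, "decay_mask", [False] * len(ps))
            for p, g, m in zip(ps, gs, masks):
                out.append((p, g, m))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _, _ in self.parameters())

    def l2_penalty(self) -> float:
        return float(sum((p ** 2).sum() for p, _, m in self.parameters() if m))

    def state(self) -> list:
        return [p.copy() for p, _, _ in self.parameters()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        for (p, _, _), s in zip(self.parameters(), state):
            p[...] = s


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _, _ in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g, decay) in enumerate(self.model.parameters()):
            grad = g + (2.0 * self.wd * p if decay and self.wd else 0.0)
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad * grad
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, model: Sequential, lr: float = 1e-3, weight_decay: float = 0.0):
        self.model = model
        self.lr = lr
        self.wd = weight_decay

    def step(self) -> None:
        for p, g, decay in self.model.parameters():
            grad = g + (2.0 * self.wd * p if decay and self.wd else 0.0)
            p -= self.lr * grad
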