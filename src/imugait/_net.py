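"""Minimal 1-D convolutional network engine (NumPy, CPU).

Implements exactly the building blocks the gait classifiers need —
1-D convolution (valid padding, stride 1), ReLU, max pooling, global
average pooling, dense layers, inverted dropout, a channel-branching
container, softmax cross-entropy and Adam — with hand-written backward
passes.  Convolution is evaluated as an im2col matrix product so the heavy
lifting stays inside BLAS; float32 throughout.

All randomness (initialisation, dropout masks) flows from generators
handed in by the caller, so training is reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "ReLU", "MaxPool1D", "GlobalAvgPool", "Dense",
           "Dropout", "Sequential", "ChannelBranches", "Network", "Adam",
           "softmax"]


class Layer:
    """Base layer: parameters and their gradients are parallel lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1D(Layer):
    """Valid 1-D convolution, stride 1: (B, L, Cin) -> (B, L-k+1, F)."""

    def __init__(self, c_in: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        self.c_in, self.filters, self.kernel = c_in, filters, kernel
        self.W = _glorot(rng, kernel * c_in, filters,
                         (kernel * c_in, filters))
        self.b = np.zeros(filters, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (B, Lout, Cin, k) view -> (B, Lout, Cin*k) copy
        cols = np.lib.stride_tricks.sliding_window_view(
            x, self.kernel, axis=1)
        b, lout = cols.shape[0], cols.shape[1]
        return np.ascontiguousarray(cols).reshape(b, lout,
                                                  self.c_in * self.kernel)

    def forward(self, x, train):
        if x.shape[2] != self.c_in:
            raise ValueError(f"Conv1D expects {self.c_in} channels, "
                             f"got {x.shape[2]}")
        if x.shape[1] < self.kernel:
            raise ValueError("input shorter than convolution kernel")
        self._cols = self._im2col(x.astype(np.float32, copy=False))
        self._in_len = x.shape[1]
        return self._cols @ self.W + self.b

    def backward(self, dy):
        b, lout, _ = dy.shape
        cols2d = self._cols.reshape(b * lout, -1)
        dy2d = dy.reshape(b * lout, self.filters).astype(np.float32,
                                                         copy=False)
        self.dW[...] = cols2d.T @ dy2d
        self.db[...] = dy2d.sum(axis=0)
        dcols = (dy2d @ self.W.T).reshape(b, lout, self.c_in, self.kernel)
        dx = np.zeros((b, self._in_len, self.c_in), dtype=np.float32)
        for j in range(self.kernel):
            dx[:, j:j + lout, :] += dcols[:, :, :, j]
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; trailing remainder dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, train):
        b, l, c = x.shape
        lout = l // self.pool
        xt = x[:, :lout * self.pool].reshape(b, lout, self.pool, c)
        self._arg = xt.argmax(axis=2)
        self._shape = (b, l, c)
        return xt.max(axis=2)

    def backward(self, dy):
        b, lout, c = dy.shape
        dx = np.zeros(self._shape, dtype=np.float32)
        dxt = dx[:, :lout * self.pool].reshape(b, lout, self.pool, c)
        bi, li, ci = np.ogrid[:b, :lout, :c]
        dxt[bi, li, self._arg, ci] = dy
        return dx


class GlobalAvgPool(Layer):
    """(B, L, C) -> (B, C), mean over time."""

    def forward(self, x, train):
        self._l = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._l, axis=1) / self._l


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x.astype(np.float32, copy=False)
        return self._x @ self.W + self.b

    def backward(self, dy):
        dy = dy.astype(np.float32, copy=False)
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self._rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep) / keep
        return x * self._mask.astype(np.float32)

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def grads(self):
        return [g for lay in self.layers for g in lay.grads()]

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class ChannelBranches(Layer):
    """Route channel groups through parallel subnets; concat their features.

    ``groups`` is a partition of the input channel axis (lists of column
    indices); each subnet maps (B, L, len(group)) to (B, F_i) and the
    outputs are concatenated feature-wise.
    """

    def __init__(self, groups: list[list[int]], subnets: list[Layer]):
        if len(groups) != len(subnets):
            raise ValueError("one subnet per channel group required")
        self.groups = [np.asarray(g, dtype=np.intp) for g in groups]
        self.subnets = subnets

    def params(self):
        return [p for net in self.subnets for p in net.params()]

    def grads(self):
        return [g for net in self.subnets for g in net.grads()]

    def forward(self, x, train):
        self._n_channels = x.shape[2]
        outs = [net.forward(np.ascontiguousarray(x[:, :, g]), train)
                for g, net in zip(self.groups, self.subnets)]
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        dx = None
        start = 0
        for g, net, w in zip(self.groups, self.subnets, self._widths):
            dxg = net.backward(dy[:, start:start + w])
            if dx is None:
                dx = np.zeros(dxg.shape[:2] + (self._n_channels,),
                              dtype=np.float32)
            dx[:, :, g] = dxg
            start += w
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A layer stack ending in class logits, with softmax/CE training loss."""

    def __init__(self, stack: Sequential, n_classes: int):
        self.stack = stack
        self.n_classes = n_classes

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.stack.params()))

    def predict_proba(self, x: np.ndarray,
                      batch_size: int = 512) -> np.ndarray:
        out = [softmax(self.stack.forward(
            x[i:i + batch_size].astype(np.float32, copy=False), train=False))
            for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on one batch; leaves gradients in the layers."""
        logits = self.stack.forward(x.astype(np.float32, copy=False),
                                    train=True)
        probs = softmax(logits)
        n = x.shape[0]
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        self.stack.backward(dlogits / n)
        return loss

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.stack.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.stack.params(), weights):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
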