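"""Minimal numpy layers with explicit backward passes.

Only what the window classifiers need: 1-D convolution (same padding, unit
stride), ReLU, inverted dropout, average pooling over time, an LSTM with
full backpropagation through time, dense layers, and Adam.  Shapes follow the
convolution convention (batch, channels, time); the LSTM consumes
(batch, time, features).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution over (B, C, T) with odd kernel size."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.k = kernel_size
        fan_in = in_channels * kernel_size
        self.W = Param(glorot(rng, (out_channels, in_channels, kernel_size), fan_in, out_channels * kernel_size))
        self.b = Param(np.zeros(out_channels))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._win = sliding_window_view(xp, self.k, axis=2)  # (B, C, T, K)
        return np.einsum("bctk,fck->bft", self._win, self.W.value, optimize=True) + self.b.value[None, :, None]

    def backward(self, grad):
        self.W.grad += np.einsum("bctk,bft->fck", self._win, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        p = self.k // 2
        gp = np.pad(grad, ((0, 0), (0, 0), (self.k - 1, self.k - 1)))
        gwin = sliding_window_view(gp, self.k, axis=2)  # (B, F, T+K-1, K)
        dxp = np.einsum("bfuk,fck->bcu", gwin, self.W.value[:, :, ::-1], optimize=True)
        T = grad.shape[2]
        return dxp[:, :, p : p + T]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class AvgPool1d(Layer):
    """Non-overlapping average pooling over time; trailing remainder dropped."""

    def __init__(self, stride: int):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.s = stride

    def forward(self, x, train=False):
        if self.s == 1:
            return x
        B, C, T = x.shape
        self._T = T
        Tp = (T // self.s) * self.s
        return x[:, :, :Tp].reshape(B, C, Tp // self.s, self.s).mean(axis=3)

    def backward(self, grad):
        if self.s == 1:
            return grad
        B, C, To = grad.shape
        out = np.zeros((B, C, self._T))
        expanded = np.repeat(grad / self.s, self.s, axis=2)
        out[:, :, : To * self.s] = expanded
        return out


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))


class LSTM(Layer):
    """Single LSTM layer over (B, T, C); gate order i, f, g, o; forget bias 1."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, return_sequences: bool = False):
        self.h = hidden
        self.return_sequences = return_sequences
        self.Wx = Param(glorot(rng, (in_dim, 4 * hidden), in_dim, hidden))
        self.Wh = Param(glorot(rng, (hidden, 4 * hidden), hidden, hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.b = Param(b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=False):
        B, T, C = x.shape
        H = self.h
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            h_prev = h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            hs[:, t] = h
            self._cache.append((h_prev, c_prev, i, f, g, o, c))
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, grad):
        x = self._x
        B, T, C = x.shape
        H = self.h
        if self.return_sequences:
            dhs = grad
        else:
            dhs = np.zeros((B, T, H))
            dhs[:, -1] = grad
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c = self._cache[t]
            dh = dhs[:, t] + dh_next
            tc = np.tanh(c)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
            )
            self.Wx.grad += x[:, t].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Param(glorot(rng, (in_dim, out_dim), in_dim, out_dim))
        self.b = Param(np.zeros(out_dim))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class TimeAvg(Layer):
    """Global average over the time axis: (B, C, T) -> (B, C)."""

    def forward(self, x, train=False):
        self._T = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._T, axis=2) / self._T


class Transpose(Layer):
    """(B, C, T) <-> (B, T, C) bridge between conv and recurrent stacks."""

    def forward(self, x, train=False):
        return np.transpose(x, (0, 2, 1))

    def backward(self, grad):
        return np.transpose(grad, (0, 2, 1))


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
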