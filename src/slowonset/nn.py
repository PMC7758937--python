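"""Minimal 1-D neural-network layers with explicit backward passes.

All arrays are ``float64`` with layout ``(batch, time, channels)``.  Each
layer caches what its backward pass needs during ``forward`` and accumulates
parameter gradients into ``Param.grad``; ``backward`` returns the gradient
with respect to the layer input, so a full backward sweep also yields input
salience.  Gradient correctness is established against central finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    #: whether the L2 kernel penalty applies (convolution kernels only)
    l2: bool = False

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pads(L: int, k: int, stride: int) -> tuple[int, int, int]:
    """'same' padding: output length ceil(L / stride)."""
    out = -(-L // stride)
    total = max((out - 1) * stride + k - L, 0)
    left = total // 2
    return out, left, total - left


def _conv1d(x: np.ndarray, w: np.ndarray, stride: int,
            pad_left: int, pad_right: int) -> np.ndarray:
    """Correlate ``x (B, L, Cin)`` with ``w (k, Cin, Cout)``."""
    xp = np.pad(x, ((0, 0), (pad_left, pad_right), (0, 0)))
    patches = sliding_window_view(xp, w.shape[0], axis=1)  # (B, L', Cin, k)
    patches = patches[:, ::stride]
    return np.tensordot(patches, w, axes=([3, 2], [0, 1]))


class Conv1D(Layer):
    """Same-padded 1-D convolution, optional stride, bias by default."""

    def __init__(self, cin: int, cout: int, k: int, *, stride: int = 1,
                 bias: bool = True, name: str = "conv",
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * cin))  # He initialization
        self.w = Param(f"{name}.w", rng.normal(0.0, scale, (k, cin, cout)),
                       l2=True)
        self.b = Param(f"{name}.b", np.zeros(cout)) if bias else None
        self.stride = stride
        self.k = k
        self._x: Optional[np.ndarray] = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        _, self._pl, self._pr = _same_pads(x.shape[1], self.k, self.stride)
        y = _conv1d(x, self.w.value, self.stride, self._pl, self._pr)
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, k, s = self._x, self.k, self.stride
        B, L, cin = x.shape
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 1))
        xp = np.pad(x, ((0, 0), (self._pl, self._pr), (0, 0)))
        patches = sliding_window_view(xp, k, axis=1)[:, ::s]  # (B,out,Cin,k)
        self.w.grad += np.tensordot(
            dy, patches, axes=([0, 1], [0, 1])
        ).transpose(2, 1, 0)  # (cout, Cin, k) -> (k, Cin, cout)
        # input gradient: full correlation of the stride-dilated dy with
        # the kernel flipped along the tap axis
        out = dy.shape[1]
        dy_up = np.zeros((B, (out - 1) * s + 1, dy.shape[2]),
                         dtype=dy.dtype)
        dy_up[:, ::s] = dy
        dyp = np.pad(dy_up, ((0, 0), (k - 1, k - 1), (0, 0)))
        pat = sliding_window_view(dyp, k, axis=1)  # (B, M, Cout, k)
        dxp = np.tensordot(pat, self.w.value[::-1], axes=([3, 2], [0, 2]))
        return dxp[:, self._pl:self._pl + L]


class BatchNorm(Layer):
    """Per-channel batch normalization over the batch and time axes."""

    def __init__(self, ch: int, *, momentum: float = 0.99, eps: float = 1e-3,
                 name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(ch))
        self.beta = Param(f"{name}.beta", np.zeros(ch))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._training = training
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        g = self.gamma.value
        if not self._training:
            return dy * g * istd
        N = dy.shape[0] * dy.shape[1]
        dxhat = dy * g
        return (istd / N) * (
            N * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class BlurPool(Layer):
    """Anti-aliased downsampling: fixed low-pass taps (reflect padding),
    then keep every second sample starting at index 0."""

    def __init__(self, taps: np.ndarray):
        self.taps = np.asarray(taps, dtype=np.float64)
        if self.taps.ndim != 1 or self.taps.shape[0] % 2 == 0:
            raise ValueError("taps must be a 1-D odd-length kernel")

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] % 2:
            raise ValueError(f"temporal length {x.shape[1]} must be even")
        self._L = x.shape[1]
        r = self.taps.shape[0] // 2
        xp = np.concatenate(
            [x[:, r:0:-1], x, x[:, -2:-2 - r:-1]], axis=1)
        pat = sliding_window_view(xp, self.taps.shape[0], axis=1)
        y = pat @ self.taps          # (B, L, C)
        return y[:, ::2]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L, r = self._L, self.taps.shape[0] // 2
        B, _, C = dy.shape
        dconv = np.zeros((B, L, C), dtype=dy.dtype)
        dconv[:, ::2] = dy
        k = self.taps.shape[0]
        dp = np.pad(dconv, ((0, 0), (k - 1, k - 1), (0, 0)))
        pat = sliding_window_view(dp, k, axis=1)
        dxp = pat @ self.taps[::-1]   # (B, L + 2r, C)
        dx = dxp[:, r:r + L].copy()
        # fold reflect-padding gradients back
        for j in range(1, r + 1):
            dx[:, j] += dxp[:, r - j]
            dx[:, L - 1 - j] += dxp[:, r + L - 1 + j]
        return dx


class MaxPool2(Layer):
    """Non-overlapping temporal max pooling with width and stride 2."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] % 2:
            raise ValueError(f"temporal length {x.shape[1]} must be even")
        B, L, C = x.shape
        pairs = x.reshape(B, L // 2, 2, C)
        self._arg = pairs.argmax(axis=2)  # (B, L/2, C)
        self._shape = x.shape
        return pairs.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, C = self._shape
        dx = np.zeros((B, L // 2, 2, C), dtype=dy.dtype)
        np.put_along_axis(dx, self._arg[:, :, None, :], dy[:, :, None, :],
                          axis=2)
        return dx.reshape(B, L, C)


class GlobalMaxPool(Layer):
    """Per-channel maximum over the time axis: (B, L, C) -> (B, C)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._arg = x.argmax(axis=1)   # (B, C)
        self._shape = x.shape
        return x.max(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dy.dtype)
        np.put_along_axis(dx, self._arg[:, None, :], dy[:, None, :], axis=1)
        return dx


class Dense(Layer):
    def __init__(self, cin: int, cout: int, *, bias: bool = True,
                 name: str = "dense",
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.w = Param(f"{name}.w", rng.normal(0.0, scale, (cin, cout)))
        self.b = Param(f"{name}.b", np.zeros(cout)) if bias else None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        y = x @ self.w.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
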