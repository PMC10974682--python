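from __future__ import annotations

import numpy as np

from .core import Layer, Param, glorot, apply_activation, activation_grad

__all__ = ["Dense", "Conv1D", "MaxPool1D", "Flatten"]


class Dense(Layer):
    """Affine map on the last axis, optionally followed by an activation.

    Accepts inputs of any rank >= 2 (applied per position, matching the
    usual dense-on-sequence behaviour)."""

    def __init__(self, in_dim: int, units: int, activation: str = "linear",
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        self.W = Param(glorot(rng, (in_dim, units), in_dim, units), f"{name}.W")
        self.b = Param(np.zeros(units), f"{name}.b")
        self.activation = activation
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        z = x @ self.W.value + self.b.value
        y = apply_activation(z, self.activation)
        self._z, self._y = z, y
        return y

    def backward(self, grad):
        dz = grad * activation_grad(self._z, self._y, self.activation)
        flat_x = self._x.reshape(-1, self._x.shape[-1])
        flat_dz = dz.reshape(-1, dz.shape[-1])
        self.W.grad += flat_x.T @ flat_dz
        self.b.grad += flat_dz.sum(axis=0)
        return dz @ self.W.value.T


class Conv1D(Layer):
    """1-D convolution over the time axis, channels last, valid padding.

    Input (B, T, C_in) -> output (B, T - k + 1, filters)."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 activation: str = "relu",
                 rng: np.random.Generator | None = None, name: str = "conv1d"):
        if kernel < 1:
            raise ValueError("kernel size must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.W = Param(glorot(rng, (kernel, in_channels, filters),
                              kernel * in_channels, filters), f"{name}.W")
        self.b = Param(np.zeros(filters), f"{name}.b")
        self.kernel = kernel
        self.activation = activation
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        B, T, C = x.shape
        k = self.kernel
        if T < k:
            raise ValueError(
                f"{self.name}: input length {T} is shorter than the kernel "
                f"size {k}")
        To = T - k + 1
        z = np.broadcast_to(self.b.value, (B, To, self.W.value.shape[2])).copy()
        for j in range(k):
            z += x[:, j:j + To, :] @ self.W.value[j]
        self._x, self._z = x, z
        y = apply_activation(z, self.activation)
        self._y = y
        return y

    def backward(self, grad):
        dz = grad * activation_grad(self._z, self._y, self.activation)
        x = self._x
        k = self.kernel
        To = dz.shape[1]
        dx = np.zeros_like(x)
        for j in range(k):
            xs = x[:, j:j + To, :]
            self.W.grad[j] += np.einsum("btc,btf->cf", xs, dz)
            dx[:, j:j + To, :] += dz @ self.W.value[j].T
        self.b.grad += dz.sum(axis=(0, 1))
        return dx


class MaxPool1D(Layer):
    """Max pooling over the time axis: window ``size``, step ``stride``."""

    def __init__(self, size: int = 2, stride: int | None = None,
                 name: str = "maxpool1d"):
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size
        self.stride = stride if stride is not None else size
        self.name = name

    def forward(self, x, train=False):
        B, T, C = x.shape
        if T < self.size:
            raise ValueError(
                f"{self.name}: input length {T} shorter than pool size "
                f"{self.size}")
        To = (T - self.size) // self.stride + 1
        y = np.empty((B, To, C))
        arg = np.empty((B, To, C), dtype=int)
        for i in range(To):
            s = i * self.stride
            win = x[:, s:s + self.size, :]
            arg[:, i, :] = np.argmax(win, axis=1)
            y[:, i, :] = np.max(win, axis=1)
        self._shape = x.shape
        self._arg = arg
        return y

    def backward(self, grad):
        B, To, C = grad.shape
        dx = np.zeros(self._shape)
        bidx = np.arange(B)[:, None]
        cidx = np.arange(C)[None, :]
        for i in range(To):
            s = i * self.stride
            np.add.at(dx[:, s:s + self.size, :],
                      (bidx, self._arg[:, i, :], cidx), grad[:, i, :])
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)
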