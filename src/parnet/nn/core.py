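from __future__ import annotations

import numpy as np

__all__ = ["Param", "Layer", "Sequential", "glorot"]


def glorot(rng: np.random.Generator, shape: tuple[int, ...],
           fan_in: int | None = None, fan_out: int | None = None) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    if fan_in is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
    if fan_out is None:
        fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name", "trainable")

    def __init__(self, value: np.ndarray, name: str = "", trainable: bool = True):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = trainable

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    """Base layer: forward caches whatever backward needs; backward
    accumulates parameter gradients and returns the input gradient."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))


class Sequential(Layer):
    def __init__(self, layers: list[Layer], name: str = "sequential"):
        self.layers = list(layers)
        self.name = name

    def params(self) -> list[Param]:
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


def apply_activation(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return z
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {kind!r}")


def activation_grad(z: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    """d(activation)/dz expressed via cached pre/post-activation values."""
    if kind == "linear":
        return np.ones_like(z)
    if kind == "relu":
        return (z > 0).astype(float)
    if kind == "tanh":
        return 1.0 - y * y
    raise ValueError(f"unknown activation {kind!r}")
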