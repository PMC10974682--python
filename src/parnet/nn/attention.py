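"""Self-attention feature-selection module (SAM).

The fused feature vector is viewed as a (G x P) grid; a scoring function
produces one score per grid position from the features along the
normalisation axis, the scores are softmax-normalised over that axis and the
features are reweighted elementwise.  In the dual-stream classifier the grid
is (D x 1) — both streams are flat when concatenated — so attention selects
among feature *dimensions*; a per-timestep grid works the same way.

The reweighted output is rescaled by G so that uniform attention is the
identity: softmax weights sum to one over G positions, and without the
rescale a constant input would be shrunk by 1/G, which couples the scale of
downstream layers to the grid size.  The weights the module reports are the
normalised ones (they sum to 1).
"""

from __future__ import annotations

import numpy as np

from .core import Layer, Param, glorot

__all__ = ["SelfAttention"]


def _softmax(s, axis):
    m = s.max(axis=axis, keepdims=True)
    e = np.exp(s - m)
    return e / e.sum(axis=axis, keepdims=True)


class SelfAttention(Layer):
    """Score -> softmax -> reweight, over axis G of a (batch, G, P) grid.

    score_fn:
      * ``"dense"``  – per-position affine scoring with learned weights
        shared across the P dimensions: S[:, g, p] = w_g * x[:, g, p] + b_g
        (the default; one score and one weight per grid position).
        Initialised at w = b = 0, so the untrained module attends uniformly
        and (with the mean-preserving rescale) passes features through
        unchanged; training learns which positions to amplify;
      * ``"dense_full"`` – a full dense layer over the G axis:
        S[:, :, p] = A @ x[:, :, p] + b with A of shape (G, G);
      * ``"identity"`` – scores are the features themselves;
      * ``"dot"``    – scaled dot-product of each position with the mean
        feature along G.

    Flat (batch, D) inputs are treated as a (D, 1) grid and flattened back.
    """

    def __init__(self, grid_len: int, score_fn: str = "dense",
                 rescale: bool = True,
                 rng: np.random.Generator | None = None,
                 name: str = "attention"):
        if score_fn not in ("dense", "dense_full", "identity", "dot"):
            raise ValueError(f"unknown score_fn {score_fn!r}")
        rng = rng or np.random.default_rng(0)
        self.grid_len = grid_len
        self.score_fn = score_fn
        self.rescale = rescale
        self.name = name
        if score_fn == "dense":
            self.A = Param(np.zeros(grid_len), f"{name}.w")
            self.bias = Param(np.zeros(grid_len), f"{name}.b")
        elif score_fn == "dense_full":
            self.A = Param(glorot(rng, (grid_len, grid_len)), f"{name}.A")
            self.bias = Param(np.zeros(grid_len), f"{name}.b")
        self.last_weights: np.ndarray | None = None

    def params(self):
        if self.score_fn in ("dense", "dense_full"):
            return [self.A, self.bias]
        return []

    def _scores(self, x):
        if self.score_fn == "identity":
            return x
        if self.score_fn == "dot":
            m = x.mean(axis=1, keepdims=True)
            return x * m / np.sqrt(self.grid_len)
        if self.score_fn == "dense":
            return x * self.A.value[None, :, None] \
                + self.bias.value[None, :, None]
        if x.shape[2] == 1:  # flat grid: plain GEMM path
            return (x[:, :, 0] @ self.A.value.T + self.bias.value)[:, :, None]
        return np.einsum("gh,bhp->bgp", self.A.value, x) \
            + self.bias.value[None, :, None]

    def forward(self, x, train=False):
        self._flat = x.ndim == 2
        if self._flat:
            x = x[:, :, None]
        if x.shape[1] != self.grid_len:
            raise ValueError(
                f"{self.name}: grid axis {x.shape[1]} != configured "
                f"{self.grid_len}")
        s = self._scores(x)
        if not np.all(np.isfinite(s)):
            raise FloatingPointError(f"{self.name}: non-finite attention scores")
        w = _softmax(s, axis=1)
        self._x, self._w = x, w
        self.last_weights = w
        scale = self.grid_len if self.rescale else 1.0
        y = w * x * scale
        return y[:, :, 0] if self._flat else y

    def backward(self, grad):
        if self._flat:
            grad = grad[:, :, None]
        x, w = self._x, self._w
        scale = self.grid_len if self.rescale else 1.0
        g = grad * scale
        dw = g * x
        dx = g * w
        # softmax jacobian over axis 1
        ds = w * (dw - (dw * w).sum(axis=1, keepdims=True))
        if self.score_fn == "identity":
            dx = dx + ds
        elif self.score_fn == "dot":
            G = self.grid_len
            m = x.mean(axis=1, keepdims=True)
            dx = dx + ds * m / np.sqrt(G)
            dm = (ds * x / np.sqrt(G)).sum(axis=1, keepdims=True)
            dx = dx + dm / G
        elif self.score_fn == "dense":
            self.A.grad += (ds * x).sum(axis=(0, 2))
            self.bias.grad += ds.sum(axis=(0, 2))
            dx = dx + ds * self.A.value[None, :, None]
        elif x.shape[2] == 1:  # dense_full, flat grid: plain GEMM path
            ds2, x2 = ds[:, :, 0], x[:, :, 0]
            self.A.grad += ds2.T @ x2
            self.bias.grad += ds2.sum(axis=0)
            dx = dx + (ds2 @ self.A.value)[:, :, None]
        else:
            self.A.grad += np.einsum("bgp,bhp->gh", ds, x)
            self.bias.grad += ds.sum(axis=(0, 2))
            dx = dx + np.einsum("gh,bgp->bhp", self.A.value, ds)
        return dx[:, :, 0] if self._flat else dx
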