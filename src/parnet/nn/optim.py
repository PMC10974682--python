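from __future__ import annotations

import numpy as np

from .core import Param

__all__ = ["Adam"]

try:  # fused single-pass update; the pure-NumPy path is the fallback
    import numba

    @numba.njit(cache=True, fastmath=False)
    def _adam_update(p, g, m, v, lr, b1, b2, eps, bc1, bc2):  # pragma: no cover
        for i in range(p.size):
            gi = g[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            p[i] -= lr * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)
            g[i] = 0.0

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class Adam:
    """Adaptive-moment estimation with bias correction (the standard recipe).

    ``step`` consumes and clears the accumulated gradients, so a training
    loop is forward -> backward -> step.
    """

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if _HAVE_NUMBA:
                _adam_update(p.value.ravel(), p.grad.ravel(), m.ravel(),
                             v.ravel(), self.lr, b1, b2, self.eps, bc1, bc2)
            else:
                g = p.grad
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                p.grad[...] = 0.0
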