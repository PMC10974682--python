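from __future__ import annotations

import numpy as np

__all__ = ["softmax", "softmax_cross_entropy"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    m = logits.max(axis=axis, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy with the fused softmax gradient.

    Returns (loss, dloss/dlogits); the gradient is (p - y)/B, numerically
    exact regardless of logit scale.
    """
    B = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.sum(onehot * np.log(p + eps)) / B
    grad = (p - onehot) / B
    return float(loss), grad
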