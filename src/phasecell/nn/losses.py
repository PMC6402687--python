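"""Loss functions returning (loss, gradient-w.r.t.-input)."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch; ``labels`` are integer class indices."""
    B = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(B), labels] + eps).mean()
    g = p.copy()
    g[np.arange(B), labels] -= 1.0
    return float(loss), g / B


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw scores (numerically stable form)."""
    z = logits.reshape(-1)
    y = targets.reshape(-1).astype(z.dtype)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    g = (p - y) / z.size
    return float(loss.mean()), g.reshape(logits.shape)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean BCE on probabilities; ``p`` must lie strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    y = np.asarray(y, dtype=float)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
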