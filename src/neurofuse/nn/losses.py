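"""Cross-entropy loss, both as a training criterion and as the bare formula."""

from __future__ import annotations

import numpy as np

from .core import DTYPE, Module


def log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def softmax(z: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(z))


def cross_entropy(q: np.ndarray, p: np.ndarray, clamp_eps: float | None = None) -> float:
    """Cross entropy L = sum_x p(x) log(1/q(x)), averaged over the batch.

    ``q`` are predicted class probabilities, ``p`` the true distribution
    (one-hot allowed). Where ``p > 0`` and ``q == 0`` the loss is infinite
    unless ``clamp_eps`` is given, in which case q is floored at that value.
    """
    q = np.atleast_2d(np.asarray(q, dtype=np.float64))
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    if q.shape != p.shape:
        raise ValueError(f"shape mismatch {q.shape} vs {p.shape}")
    if np.any(q < 0) or np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("q rows must sum to 1")
    if clamp_eps is not None:
        q = np.maximum(q, clamp_eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(np.where(q > 0, q, 1.0)), 0.0)
        terms = np.where((p > 0) & (q == 0), -np.inf, terms)
    return float(-terms.sum(axis=1).mean())


class SoftmaxCrossEntropy(Module):
    """Numerically stable softmax + cross entropy against integer labels."""

    def forward(self, logits: np.ndarray, targets: np.ndarray) -> float:
        logits = np.asarray(logits, dtype=DTYPE)
        targets = np.asarray(targets, dtype=np.int64)
        logp = log_softmax(logits.astype(np.float64))
        n = logits.shape[0]
        loss = -logp[np.arange(n), targets].mean()
        self._cache = (np.exp(logp).astype(DTYPE), targets, n)
        return float(loss)

    def backward(self) -> np.ndarray:
        probs, targets, n = self._cache
        grad = probs.copy()
        grad[np.arange(n), targets] -= 1.0
        return grad / n
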