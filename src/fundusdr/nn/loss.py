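"""Multinomial cross-entropy over the four patch classes.

The training criterion is the mean negative log-likelihood of the true
class,

    L_c = -(1/|C|) * sum_i ln p(D_i | C_i),

with probabilities floored at a small epsilon for numerical safety.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidInputError

#: Probability floor inside the logarithm.
EPS = 1e-12


def cross_entropy_loss(predicted_probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability assigned to the true class.

    Parameters
    ----------
    predicted_probs
        ``(N, K)`` rows of class probabilities; each row must be nonnegative
        and sum to 1 within 1e-5.
    labels
        ``(N,)`` integer class indices in ``[0, K)``.
    """
    probs = np.asarray(predicted_probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim == 1:
        probs = probs[None]
    if labels.ndim == 0:
        labels = labels[None]
    n, k = probs.shape
    if n < 1:
        raise InvalidInputError("need at least one sample")
    if labels.shape[0] != n:
        raise InvalidInputError("labels/probabilities length mismatch")
    if np.any(labels < 0) or np.any(labels >= k):
        raise InvalidInputError(f"label index out of range [0, {k})")
    if np.any(probs < -1e-9):
        raise InvalidInputError("probabilities must be nonnegative")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-5):
        raise InvalidInputError("probability rows must sum to 1")
    p_true = probs[np.arange(n), labels]
    return float(-np.mean(np.log(np.maximum(p_true, EPS))))


def softmax_cross_entropy_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of the mean cross-entropy w.r.t. the logits: (p - y)/N."""
    n = probs.shape[0]
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return grad / n
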