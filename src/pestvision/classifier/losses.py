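"""Classification losses: softmax cross-entropy and one-versus-all hinge.

Both accept a single score vector or an (N, K) batch and return the
(mean) loss together with the gradient w.r.t. the scores, so they plug
straight into back-propagation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax_loss", "hinge_loss_ova", "softmax_probs"]


def _as_batch(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    single = scores.ndim == 1
    if single:
        scores = scores[None, :]
        labels = np.array([labels])
    else:
        labels = np.asarray(labels)
    return scores, labels, single


def softmax_probs(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_loss(scores, labels):
    """Cross-entropy of softmax probabilities.

    Returns ``(loss, grad)`` with ``grad = p - one_hot(label)`` (averaged
    over the batch when given one).
    """
    scores, labels, single = _as_batch(scores, labels)
    n = scores.shape[0]
    p = softmax_probs(scores)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return float(loss), grad[0] * n if single else grad


def hinge_loss_ova(scores, labels):
    """Linear one-versus-all hinge loss with targets +/-1.

    Per sample: ``max(0, 1 - s_y) + sum_{c != y} max(0, 1 + s_c)``.
    Returns the (mean) loss and its (sub)gradient.
    """
    scores, labels, single = _as_batch(scores, labels)
    n, k = scores.shape
    targets = -np.ones((n, k))
    targets[np.arange(n), labels] = 1.0
    margins = 1.0 - targets * scores
    active = margins > 0
    loss = np.where(active, margins, 0.0).sum(axis=1).mean()
    grad = np.where(active, -targets, 0.0) / n
    return float(loss), grad[0] * n if single else grad
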