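"""Softmax discriminant classifier.

Linear per-class scores z_k = w_k·x + b_k pass through a softmax to class
probabilities; weights and biases are trained by full-batch gradient descent
on the cross-entropy loss.  An optional L2 penalty on the weights is
available (coefficient ``l2``); if the loss diverges the learning rate is
halved up to five times before giving up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from ..errors import FitError
from .base import check_xy, decode_labels


@dataclass
class SDCModel:
    weights: np.ndarray  # (K, d)
    biases: np.ndarray  # (K,)
    learning_rate: float
    l2: float
    loss_trace: list[float] = field(default_factory=list)

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, float)) @ self.weights.T + self.biases


def _loss(Z: np.ndarray, y: np.ndarray, W: np.ndarray, l2: float) -> float:
    logp = Z - logsumexp(Z, axis=1, keepdims=True)
    ce = -float(np.mean(logp[np.arange(len(y)), y]))
    return ce + 0.5 * l2 * float(np.sum(W * W))


def sdc_fit(
    X: np.ndarray,
    labels: np.ndarray,
    learning_rate: float = 0.5,
    epochs: int = 1000,
    tol: float = 1e-8,
    l2: float = 0.0,
) -> SDCModel:
    """Gradient-descent fit; expects standardized features.

    Stops when the loss change falls below ``tol`` or after ``epochs``
    full-batch updates.
    """
    X, y = check_xy(X, labels, require_both=False)
    n, d = X.shape
    k = 2
    onehot = np.eye(k)[y]

    alpha = float(learning_rate)
    for _attempt in range(6):
        W = np.zeros((k, d))
        b = np.zeros(k)
        trace: list[float] = []
        prev = np.inf
        diverged = False
        for _ in range(epochs):
            Z = X @ W.T + b
            loss = _loss(Z, y, W, l2)
            if not np.isfinite(loss) or loss > prev + 1e-6:
                diverged = True
                break
            trace.append(loss)
            if abs(prev - loss) < tol:
                break
            prev = loss
            P = softmax(Z, axis=1)
            grad = P - onehot  # (n, k)
            W -= alpha * (grad.T @ X / n + l2 * W)
            b -= alpha * grad.mean(axis=0)
        if not diverged:
            return SDCModel(W, b, alpha, l2, trace)
        alpha *= 0.5
    raise FitError("softmax training diverged even after halving the learning rate 5x")


def sdc_proba(model: SDCModel, X: np.ndarray) -> np.ndarray:
    return softmax(model.scores(X), axis=1)


def sdc_predict(model: SDCModel, X: np.ndarray) -> np.ndarray:
    p = sdc_proba(model, X)
    return decode_labels(np.argmax(p, axis=1))  # ties -> lowest index (Adeno)
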