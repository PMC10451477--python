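"""Naive Bayes classifier with Gaussian per-feature likelihoods.

The posterior of class C factorizes over features under the conditional
independence assumption; for real-valued expression features each factor is
a univariate Gaussian whose variance is floored at ``alpha`` times the
per-feature pooled variance (alpha = 0.06 by default).  Priors are the class
fractions; ties break to Adeno, which is also the majority class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .base import check_xy, decode_labels


@dataclass
class NBCModel:
    log_priors: np.ndarray  # (2,), order [Adeno, Meso]
    means: np.ndarray  # (2, d)
    variances: np.ndarray  # (2, d), floored
    alpha: float


def nbc_fit(X: np.ndarray, labels: np.ndarray, alpha: float = 0.06) -> NBCModel:
    X, y = check_xy(X, labels)
    d = X.shape[1]
    pooled_var = X.var(axis=0)
    # guard features constant everywhere: keep the likelihood proper
    floor = alpha * np.where(pooled_var > 0, pooled_var, 1.0)
    means = np.empty((2, d))
    variances = np.empty((2, d))
    priors = np.empty(2)
    for cls in (0, 1):
        Xc = X[y == cls]
        priors[cls] = Xc.shape[0] / X.shape[0]
        means[cls] = Xc.mean(axis=0)
        variances[cls] = np.maximum(Xc.var(axis=0), floor)
    return NBCModel(np.log(priors), means, variances, alpha)


def nbc_joint_log_likelihood(model: NBCModel, X: np.ndarray) -> np.ndarray:
    """(n, 2) log p(C) + sum_i log p(x_i | C)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], 2))
    for cls in (0, 1):
        var = model.variances[cls]
        ll = -0.5 * (
            np.log(2.0 * np.pi * var) + (X - model.means[cls]) ** 2 / var
        )
        out[:, cls] = model.log_priors[cls] + ll.sum(axis=1)
    return out


def nbc_posterior(model: NBCModel, X: np.ndarray) -> np.ndarray:
    jll = nbc_joint_log_likelihood(model, X)
    return np.exp(jll - logsumexp(jll, axis=1, keepdims=True))


def nbc_predict(model: NBCModel, X: np.ndarray) -> np.ndarray:
    jll = nbc_joint_log_likelihood(model, X)
    return decode_labels(np.argmax(jll, axis=1))
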