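"""Gaussian mixture model classifier, fit by expectation-maximization.

One K-component full-covariance mixture is fitted per class by maximum
likelihood; prediction weighs each class's mixture likelihood by the class
prior.  EM stops when the log-likelihood change drops below ``tol`` or after
``max_iter`` iterations.  Collapsing components (empty responsibility or a
covariance that stays singular after a ridge) are reseeded once, then raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ..errors import FitError, InvalidConfigError
from .base import check_xy, decode_labels


def gaussian_pdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Multivariate normal density (2π)^(−n/2)|Ԑ|^(−1/2)exp(−½ δᵀԐ⁻¹δ)."""
    return float(np.exp(gaussian_logpdf(np.atleast_2d(x), mean, cov)[0]))


def gaussian_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    n = mean.shape[0]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        try:
            chol = np.linalg.cholesky(cov + 1e-6 * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise FitError("covariance matrix is not positive definite") from exc
    diff = X - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = np.sum(sol * sol, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + maha)


@dataclass
class Mixture:
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)

    def component_logpdf(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, K) log of π_k · N(x; μ_k, Ԑ_k)."""
        parts = [
            np.log(self.weights[k]) + gaussian_logpdf(X, self.means[k], self.covariances[k])
            for k in range(len(self.weights))
        ]
        return np.stack(parts, axis=1)

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        lp = self.component_logpdf(X)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return logsumexp(self.component_logpdf(X), axis=1)


def _fit_mixture(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    reg_covar: float,
    _reseeded: bool = False,
) -> Mixture:
    n, d = X.shape
    if k == 1:
        # closed-form MLE: mean is exactly the sample mean
        mean = X.mean(axis=0)
        cov = np.cov(X.T, bias=True).reshape(d, d) + reg_covar * np.eye(d)
        mix = Mixture(np.array([1.0]), mean[None, :], cov[None, :, :])
        mix.loglik_trace.append(float(mix.score_samples(X).sum()))
        return mix

    # k-means++-style seeding: spread the initial means apart
    first = int(rng.integers(n))
    chosen = [first]
    for _ in range(k - 1):
        d2 = np.min(
            np.sum((X[:, None, :] - X[chosen][None, :, :]) ** 2, axis=-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            chosen.append(int(rng.integers(n)))
        else:
            chosen.append(int(rng.choice(n, p=d2 / total)))
    means = X[chosen].copy()
    base_cov = np.cov(X.T, bias=True).reshape(d, d) + reg_covar * np.eye(d)
    covs = np.repeat(base_cov[None, :, :], k, axis=0)
    weights = np.full(k, 1.0 / k)
    mix = Mixture(weights, means, covs)

    prev = -np.inf
    for _ in range(max_iter):
        resp = mix.responsibilities(X)
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            if _reseeded:
                raise FitError("mixture component collapsed during EM")
            return _fit_mixture(X, k, rng, tol, max_iter, reg_covar, _reseeded=True)
        mix.weights = nk / n
        mix.means = (resp.T @ X) / nk[:, None]
        for j in range(k):
            diff = X - mix.means[j]
            cov = (resp[:, j][:, None] * diff).T @ diff / nk[j]
            mix.covariances[j] = cov + reg_covar * np.eye(d)
        ll = float(mix.score_samples(X).sum())
        mix.loglik_trace.append(ll)
        if abs(ll - prev) < tol:
            break
        prev = ll
    return mix


@dataclass
class GMMModel:
    mixtures: dict[str, Mixture]
    log_priors: dict[str, float]
    n_components: int


def gmm_fit(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 1000,
    reg_covar: float = 1e-6,
    seed: int = 0,
) -> GMMModel:
    """Fit one mixture per class; class priors are the class fractions."""
    X, y = check_xy(X, labels)
    if n_components < 1:
        raise InvalidConfigError("n_components must be >= 1")
    rng = np.random.default_rng(seed)
    mixtures: dict[str, Mixture] = {}
    log_priors: dict[str, float] = {}
    for cls, name in enumerate(("Adeno", "Meso")):
        Xc = X[y == cls]
        if Xc.shape[0] < n_components:
            raise InvalidConfigError(
                f"class {name} has {Xc.shape[0]} samples < K={n_components}"
            )
        mixtures[name] = _fit_mixture(Xc, n_components, rng, tol, max_iter, reg_covar)
        log_priors[name] = float(np.log(Xc.shape[0] / X.shape[0]))
    return GMMModel(mixtures=mixtures, log_priors=log_priors, n_components=n_components)


def gmm_class_log_likelihood(model: GMMModel, X: np.ndarray) -> np.ndarray:
    """(n_samples, 2) prior-weighted class log-likelihoods [Adeno, Meso]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = [
        model.log_priors[name] + model.mixtures[name].score_samples(X)
        for name in ("Adeno", "Meso")
    ]
    return np.stack(cols, axis=1)


def gmm_posterior(model: GMMModel, X: np.ndarray) -> np.ndarray:
    ll = gmm_class_log_likelihood(model, X)
    return np.exp(ll - logsumexp(ll, axis=1, keepdims=True))


def gmm_predict(model: GMMModel, X: np.ndarray) -> np.ndarray:
    ll = gmm_class_log_likelihood(model, X)
    # argmax with ties to the lowest class index (Adeno)
    return decode_labels(np.argmax(ll, axis=1))
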