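"""Soft-margin support vector machine trained by sequential minimal optimization.

Three kernels are provided:

* linear      K(x,z) = x·z
* polynomial  K(x,z) = (γ x·z + r)^d
* RBF         K(x,z) = exp(−|x−z|² / (2σ²))

The dual problem is solved with a simplified SMO sweep (pairwise coordinate
ascent over the α_i within the box [0, C]) to a KKT tolerance; Adeno maps to
+1 and Meso to −1, and a zero decision value resolves to Adeno.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import FitError, InvalidConfigError
from .base import check_xy, decode_labels

KERNELS = ("linear", "poly", "rbf")


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "rbf"
    gamma: float = 1.0  # polynomial scale
    coef0: float = 0.0  # polynomial independent term r
    degree: int = 2  # polynomial degree d
    sigma: float = 100.0  # RBF width

    def __post_init__(self) -> None:
        if self.kind not in KERNELS:
            raise InvalidConfigError(f"unknown kernel {self.kind!r}")
        if self.kind == "rbf" and self.sigma <= 0:
            raise InvalidConfigError("RBF width sigma must be > 0")
        if self.kind == "poly" and self.degree < 1:
            raise InvalidConfigError("polynomial degree must be >= 1")

    def matrix(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        A = np.atleast_2d(np.asarray(A, float))
        B = np.atleast_2d(np.asarray(B, float))
        if self.kind == "linear":
            return A @ B.T
        if self.kind == "poly":
            return (self.gamma * (A @ B.T) + self.coef0) ** self.degree
        sq = (
            np.sum(A * A, axis=1)[:, None]
            - 2.0 * (A @ B.T)
            + np.sum(B * B, axis=1)[None, :]
        )
        return np.exp(-np.maximum(sq, 0.0) / (2.0 * self.sigma**2))


@dataclass
class SVMModel:
    kernel: KernelSpec
    C: float
    alphas: np.ndarray  # dual coefficients of the support vectors
    support_vectors: np.ndarray
    support_y: np.ndarray  # ±1
    bias: float
    n_iter: int

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        K = self.kernel.matrix(np.atleast_2d(np.asarray(X, float)), self.support_vectors)
        return K @ (self.alphas * self.support_y) + self.bias

    def weight_vector(self) -> np.ndarray:
        """Primal w for the linear kernel."""
        if self.kernel.kind != "linear":
            raise InvalidConfigError("weight vector only defined for the linear kernel")
        return (self.alphas * self.support_y) @ self.support_vectors


def svm_fit(
    X: np.ndarray,
    labels: np.ndarray,
    kernel: KernelSpec | str = "rbf",
    C: float = 1.0,
    tol: float = 1e-3,
    max_passes: int = 10,
    max_iter: int = 10_000,
    seed: int = 0,
    **kernel_params,
) -> SVMModel:
    """Solve the soft-margin dual by simplified SMO.

    ``tol`` is the KKT violation tolerance; training stops when a full
    sweep changes no α pair for ``max_passes`` consecutive passes.
    """
    if isinstance(kernel, str):
        kernel = KernelSpec(kind=kernel, **kernel_params)
    X, y01 = check_xy(X, labels)
    y = np.where(y01 == 0, 1.0, -1.0)  # Adeno -> +1
    n = X.shape[0]

    K = kernel.matrix(X, X)
    eig_min = float(np.linalg.eigvalsh((K + K.T) / 2.0).min())
    if eig_min < -1e-6 * max(1.0, float(np.abs(K).max())):
        raise FitError(
            f"{kernel.kind} kernel matrix is not positive semi-definite "
            f"(min eigenvalue {eig_min:.3g}); check the kernel parameters"
        )

    rng = np.random.default_rng(seed)
    alphas = np.zeros(n)
    b = 0.0
    passes = 0
    it = 0

    def f(i: int) -> float:
        return float(K[i] @ (alphas * y) + b)

    while passes < max_passes and it < max_iter:
        changed = 0
        for i in range(n):
            Ei = f(i) - y[i]
            if (y[i] * Ei < -tol and alphas[i] < C) or (y[i] * Ei > tol and alphas[i] > 0):
                j = int(rng.integers(n - 1))
                if j >= i:
                    j += 1
                Ej = f(j) - y[j]
                ai_old, aj_old = alphas[i], alphas[j]
                if y[i] != y[j]:
                    lo, hi = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
                else:
                    lo, hi = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
                if lo >= hi:
                    continue
                eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
                if eta >= 0:
                    continue
                aj = np.clip(aj_old - y[j] * (Ei - Ej) / eta, lo, hi)
                if abs(aj - aj_old) < 1e-7:
                    continue
                ai = ai_old + y[i] * y[j] * (aj_old - aj)
                alphas[i], alphas[j] = ai, aj
                b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] - y[j] * (aj - aj_old) * K[i, j]
                b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] - y[j] * (aj - aj_old) * K[j, j]
                if 0 < ai < C:
                    b = b1
                elif 0 < aj < C:
                    b = b2
                else:
                    b = (b1 + b2) / 2.0
                changed += 1
        it += 1
        passes = passes + 1 if changed == 0 else 0

    sv = alphas > 1e-8
    return SVMModel(
        kernel=kernel,
        C=C,
        alphas=alphas[sv],
        support_vectors=X[sv],
        support_y=y[sv],
        bias=b,
        n_iter=it,
    )


def svm_predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    d = model.decision_function(X)
    return decode_labels(np.where(d >= 0, 0, 1))  # zero -> Adeno
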