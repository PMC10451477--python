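"""Shared helpers for the binary classifiers.

All classifiers work on X of shape (n_samples, n_features) with string
labels in {"Adeno", "Meso"}.  Internally classes are ordered
[Adeno, Meso] (index 0 = Adeno); ties always break to the lowest class
index, i.e. to Adeno, for determinism.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidConfigError

CLASSES = np.array(["Adeno", "Meso"], dtype=object)


def encode_labels(labels: np.ndarray) -> np.ndarray:
    """Map labels to class indices 0 (Adeno) / 1 (Meso)."""
    labels = np.asarray(labels, dtype=object)
    out = np.where(labels == "Adeno", 0, np.where(labels == "Meso", 1, -1)).astype(int)
    if np.any(out < 0):
        bad = sorted(set(labels) - {"Adeno", "Meso"})
        raise InvalidConfigError(f"unknown labels: {bad}")
    return out


def decode_labels(idx: np.ndarray) -> np.ndarray:
    return CLASSES[np.asarray(idx, dtype=int)]


def check_xy(
    X: np.ndarray, labels: np.ndarray, require_both: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = encode_labels(labels)
    if X.ndim != 2:
        raise InvalidConfigError("X must be 2-D (samples x features)")
    if X.shape[0] != y.shape[0]:
        raise InvalidConfigError("sample count of X and labels differ")
    if require_both and len(np.unique(y)) < 2:
        raise InvalidConfigError("both classes must be present for training")
    return X, y


class Standardizer:
    """Per-feature z-scoring with zero-variance features left centred."""

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
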