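"""The seven binary classifiers and their shipped parameter defaults.

Use :func:`make_classifier` to obtain a uniform fit/predict wrapper:

========== =============================================================
name       model (defaults)
========== =============================================================
nlr        nonlinear regression (targets 0.85/0.65, k-grid on (0,1])
gmm        per-class Gaussian mixtures (K=2, EM, ridge 1e-6)
sdc        softmax discriminant (full-batch gradient descent)
nbc        Gaussian naive Bayes (variance-floor alpha = 0.06)
svm-linear SMO, linear kernel, C = 0.85
svm-poly   SMO, polynomial kernel, C = 0.76, gamma = 10, r = 0, d = 2
svm-rbf    SMO, RBF kernel, C = 1, sigma = 100
========== =============================================================
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidConfigError
from .base import CLASSES, Standardizer, check_xy, decode_labels, encode_labels
from .gmm import (
    GMMModel,
    Mixture,
    gaussian_logpdf,
    gaussian_pdf,
    gmm_class_log_likelihood,
    gmm_fit,
    gmm_posterior,
    gmm_predict,
)
from .nbc import NBCModel, nbc_fit, nbc_joint_log_likelihood, nbc_posterior, nbc_predict
from .nlr import NLRModel, cuboid_score, nlr_fit, nlr_predict
from .sdc import SDCModel, sdc_fit, sdc_predict, sdc_proba
from .svm import KernelSpec, SVMModel, svm_fit, svm_predict
from .targets import TargetMap, select_targets

CLASSIFIER_NAMES = ("nlr", "gmm", "sdc", "nbc", "svm-linear", "svm-poly", "svm-rbf")


class Classifier:
    """Uniform fit/predict facade over the seven model families."""

    def __init__(self, name: str, targets: TargetMap | None = None, **params):
        if name not in CLASSIFIER_NAMES:
            raise InvalidConfigError(
                f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}"
            )
        self.name = name
        self.targets = targets or TargetMap()
        self.params = params
        self.model_ = None

    def fit(self, X: np.ndarray, labels: np.ndarray) -> "Classifier":
        p = dict(self.params)
        if self.name == "nlr":
            self.model_ = nlr_fit(X, labels, targets=self.targets, **p)
        elif self.name == "gmm":
            p.setdefault("n_components", 2)
            self.model_ = gmm_fit(X, labels, **p)
        elif self.name == "sdc":
            self.model_ = sdc_fit(X, labels, **p)
        elif self.name == "nbc":
            p.setdefault("alpha", 0.06)
            self.model_ = nbc_fit(X, labels, **p)
        elif self.name == "svm-linear":
            p.setdefault("C", 0.85)
            self.model_ = svm_fit(X, labels, kernel="linear", **p)
        elif self.name == "svm-poly":
            p.setdefault("C", 0.76)
            kernel = KernelSpec(
                kind="poly",
                gamma=p.pop("gamma", 10.0),
                coef0=p.pop("coef0", 0.0),
                degree=p.pop("degree", 2),
            )
            self.model_ = svm_fit(X, labels, kernel=kernel, **p)
        else:  # svm-rbf
            p.setdefault("C", 1.0)
            kernel = KernelSpec(kind="rbf", sigma=p.pop("sigma", 100.0))
            self.model_ = svm_fit(X, labels, kernel=kernel, **p)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise InvalidConfigError("classifier is not fitted")
        if self.name == "nlr":
            return nlr_predict(self.model_, X)
        if self.name == "gmm":
            return gmm_predict(self.model_, X)
        if self.name == "sdc":
            return sdc_predict(self.model_, X)
        if self.name == "nbc":
            return nbc_predict(self.model_, X)
        return svm_predict(self.model_, X)

    def posterior(self, X: np.ndarray) -> np.ndarray | None:
        """(n, 2) class probabilities for the probabilistic models, else None."""
        if self.name == "gmm":
            return gmm_posterior(self.model_, X)
        if self.name == "sdc":
            return sdc_proba(self.model_, X)
        if self.name == "nbc":
            return nbc_posterior(self.model_, X)
        return None

    def observed_targets(self, X: np.ndarray) -> np.ndarray:
        """Model output mapped onto the class-target scale.

        Probabilistic models return the posterior-weighted target; the
        others return the target of the predicted class.
        """
        post = self.posterior(X)
        if post is not None:
            return post @ np.array([self.targets.t_adeno, self.targets.t_meso])
        pred = encode_labels(self.predict(X))
        return np.where(pred == 0, self.targets.t_adeno, self.targets.t_meso)


def make_classifier(name: str, targets: TargetMap | None = None, **params) -> Classifier:
    return Classifier(name, targets=targets, **params)


__all__ = [
    "CLASSES",
    "CLASSIFIER_NAMES",
    "Classifier",
    "KernelSpec",
    "GMMModel",
    "Mixture",
    "NBCModel",
    "NLRModel",
    "SDCModel",
    "SVMModel",
    "Standardizer",
    "TargetMap",
    "cuboid_score",
    "check_xy",
    "decode_labels",
    "encode_labels",
    "gaussian_logpdf",
    "gaussian_pdf",
    "gmm_class_log_likelihood",
    "gmm_fit",
    "gmm_posterior",
    "gmm_predict",
    "make_classifier",
    "nbc_fit",
    "nbc_joint_log_likelihood",
    "nbc_posterior",
    "nbc_predict",
    "nlr_fit",
    "nlr_predict",
    "sdc_fit",
    "sdc_predict",
    "sdc_proba",
    "select_targets",
    "svm_fit",
    "svm_predict",
]
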