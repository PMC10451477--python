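"""Cross-validation, confusion-matrix metrics and end-to-end experiments.

Adeno is the positive class.  The metric suite reports accuracy, precision,
recall, F1 and error rate as percentages, the Matthews correlation
coefficient in [−1, 1], and Cohen's kappa via the observed/chance agreement
pair (P_o, P_e).  Any zero denominator yields a defined 0 together with a
degenerate flag rather than an exception, so degenerate CV folds cannot
abort an experiment.

`reconstruct_confusion` inverts printed summary statistics: given accuracy,
precision and recall (in %) and the two class sizes, it brute-forces the
integer confusion matrix that matches them best — useful for recovering the
full matrix behind a published results table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from sklearn.model_selection import StratifiedKFold, KFold

from .classifiers import Standardizer, TargetMap, encode_labels, make_classifier
from .errors import InvalidConfigError
from .selection import HSConfig, PSOConfig, hs_select, make_fitness, pso_select
from .spectral import WindowSpec, spectral_features
from .synthdata import ADENO, MESO, ExpressionMatrix


# ---------------------------------------------------------------------------
# cross-validation plans
# ---------------------------------------------------------------------------


@dataclass
class CVPlan:
    fold_of: np.ndarray  # subject -> fold index
    k: int
    stratified: bool
    seed: int

    def folds(self):
        for f in range(self.k):
            test = np.flatnonzero(self.fold_of == f)
            train = np.flatnonzero(self.fold_of != f)
            yield train, test


def kfold_plan(
    labels: np.ndarray, k: int = 10, stratified: bool = True, seed: int = 0
) -> CVPlan:
    """Deterministic (stratified) k-fold assignment of subjects to folds."""
    labels = np.asarray(labels, dtype=object)
    n = labels.shape[0]
    if k < 2:
        raise InvalidConfigError("k must be >= 2")
    if stratified:
        counts = {c: int(np.sum(labels == c)) for c in set(labels)}
        small = min(counts, key=counts.get)
        if counts[small] < k:
            raise InvalidConfigError(
                f"class {small} has only {counts[small]} members, fewer than "
                f"k={k}; use a smaller k"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), labels.astype(str))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    fold_of = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(split):
        fold_of[test] = f
    return CVPlan(fold_of=fold_of, k=k, stratified=stratified, seed=seed)


def mse(observed: np.ndarray, targets: np.ndarray) -> float:
    """(1/N)·Σ(O_j − T_j)²."""
    o = np.asarray(observed, dtype=float)
    t = np.asarray(targets, dtype=float)
    if o.shape != t.shape:
        raise InvalidConfigError("observed and target shapes differ")
    if o.size == 0:
        raise InvalidConfigError("MSE of empty vectors is undefined")
    return float(np.mean((o - t) ** 2))


# ---------------------------------------------------------------------------
# confusion matrix and metric suite
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.fp, self.tn):
            if v < 0:
                raise InvalidConfigError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
        )


def confusion(true_labels: np.ndarray, predicted_labels: np.ndarray) -> ConfusionMatrix:
    """Tabulate predictions with Adeno as the positive class."""
    yt = encode_labels(np.asarray(true_labels, dtype=object))
    yp = encode_labels(np.asarray(predicted_labels, dtype=object))
    if yt.shape != yp.shape:
        raise InvalidConfigError("true/predicted label counts differ")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 0) & (yp == 1))),
        fp=int(np.sum((yt == 1) & (yp == 0))),
        tn=int(np.sum((yt == 1) & (yp == 1))),
    )


@dataclass
class MetricsReport:
    accuracy: float  # %
    precision: float  # %
    recall: float  # %
    f1: float  # %
    mcc: float
    error_rate: float  # %
    kappa: float
    p_o: float
    p_e: float
    degenerate: list[str] = field(default_factory=list)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The full confusion-matrix statistic suite.

    accuracy = (TP+TN)/N, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2TP/(2TP+FP+FN), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    error rate = (FP+FN)/N, kappa = (P_o − P_e)/(1 − P_e) with
    P_e = [(TP+FP)(TP+FN) + (FP+TN)(FN+TN)] / N².
    """
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    n = cm.total
    if n == 0:
        raise InvalidConfigError("empty confusion matrix")

    degenerate: list[str] = []

    def ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            degenerate.append(what)
            return 0.0
        return num / den

    acc = (tp + tn) / n
    prec = ratio(tp, tp + fp, "precision")
    rec = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ratio(tp * tn - fp * fn, np.sqrt(mcc_den) if mcc_den else 0.0, "mcc")
    err = (fp + fn) / n
    p_o = acc
    p_e = ((tp + fp) * (tp + fn) + (fp + tn) * (fn + tn)) / n**2
    kappa = ratio(p_o - p_e, 1.0 - p_e, "kappa")

    return MetricsReport(
        accuracy=100.0 * acc,
        precision=100.0 * prec,
        recall=100.0 * rec,
        f1=100.0 * f1,
        mcc=float(mcc),
        error_rate=100.0 * err,
        kappa=float(kappa),
        p_o=float(p_o),
        p_e=float(p_e),
        degenerate=degenerate,
    )


def reconstruct_confusion(
    accuracy: float,
    precision: float,
    recall: float,
    n_positive: int,
    n_negative: int,
) -> ConfusionMatrix:
    """Brute-force the integer confusion matrix behind printed summary rates.

    ``accuracy``, ``precision`` and ``recall`` are percentages; TP+FN is
    fixed to ``n_positive`` and FP+TN to ``n_negative``.  The candidate with
    the smallest squared mismatch against the three printed rates wins.
    """
    n = n_positive + n_negative
    best: tuple[float, ConfusionMatrix] | None = None
    for tp in range(n_positive + 1):
        fn = n_positive - tp
        for tn in range(n_negative + 1):
            fp = n_negative - tn
            acc = 100.0 * (tp + tn) / n
            prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
            rec = 100.0 * tp / n_positive
            err = (acc - accuracy) ** 2 + (prec - precision) ** 2 + (rec - recall) ** 2
            if best is None or err < best[0]:
                best = (err, ConfusionMatrix(tp, fn, fp, tn))
    return best[1]


# ---------------------------------------------------------------------------
# end-to-end experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """Stages and parameters of an extract → select → classify run."""

    classifier: str = "svm-rbf"
    classifier_params: dict = field(default_factory=dict)
    window_length: int = 4096
    hop: int = 2048
    transform_size: int = 4096
    selection: str = "none"  # none | pso | hs
    subset_size: int = 30
    selection_iterations: int = 20
    selection_population: int = 10
    cv_scheme: str = "kfold"  # kfold | split
    k: int = 10
    split_fraction: float = 0.85
    standardize: bool = True
    seed: int = 0

    def window_spec(self) -> WindowSpec:
        return WindowSpec(
            window_length=self.window_length,
            hop=self.hop,
            transform_size=self.transform_size,
        )


def _split_plan(labels: np.ndarray, fraction: float, seed: int):
    """Single stratified train/test split (train share = ``fraction``)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (ADENO, MESO):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def run_experiment(
    data: ExpressionMatrix, config: ExperimentConfig | None = None
) -> dict[str, Any]:
    """Run extract → (select) → classify with cross-validation.

    Returns a JSON-serializable report: per-fold metrics and train/test MSE,
    the pooled confusion matrix with its metric suite, and the fully
    resolved configuration.  Deterministic for a fixed config (the config's
    seed drives every random draw).
    """
    config = config or ExperimentConfig()
    data.require_both_classes()
    targets = TargetMap()

    feats = spectral_features(data, config.window_spec())
    X = feats.values.T  # subjects x features
    labels = feats.labels

    selection_note: str | None = None
    if config.selection == "none":
        selection_note = "no feature selection"
        selected = np.arange(X.shape[1])
    elif config.selection in ("pso", "hs"):
        fitness = make_fitness(X, labels, targets=targets)
        if config.selection == "pso":
            cfg = PSOConfig(
                swarm_size=config.selection_population,
                iterations=config.selection_iterations,
                subset_size=config.subset_size,
                seed=config.seed,
            )
            sel = pso_select(X, labels, cfg, fitness)
        else:
            cfg = HSConfig(
                memory_size=config.selection_population,
                iterations=config.selection_iterations,
                subset_size=config.subset_size,
                seed=config.seed,
            )
            sel = hs_select(X, labels, cfg, fitness)
        selected = sel.selected_indices
    else:
        raise InvalidConfigError(f"unknown selection method {config.selection!r}")
    X = X[:, selected]

    if config.cv_scheme == "kfold":
        plan = kfold_plan(labels, k=config.k, stratified=True, seed=config.seed)
        folds = list(plan.folds())
    elif config.cv_scheme == "split":
        folds = [_split_plan(labels, config.split_fraction, config.seed)]
    else:
        raise InvalidConfigError(f"unknown cv scheme {config.cv_scheme!r}")

    fold_reports = []
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for fold_index, (train, test) in enumerate(folds):
        try:
            Xtr, Xte = X[train], X[test]
            if config.standardize:
                sc = Standardizer().fit(Xtr)
                Xtr, Xte = sc.transform(Xtr), sc.transform(Xte)
            clf = make_classifier(
                config.classifier, targets=targets, **config.classifier_params
            )
            clf.fit(Xtr, labels[train])
            pred_tr = clf.predict(Xtr)
            pred_te = clf.predict(Xte)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'classify' failed on fold {fold_index}: {exc}"
            ) from exc
        cm = confusion(labels[test], pred_te)
        pooled = pooled + cm
        rep = metrics(cm)
        fold_reports.append(
            {
                "fold": fold_index,
                "confusion": asdict(cm),
                "metrics": asdict(rep),
                "train_mse": mse(
                    clf.observed_targets(Xtr), targets.target_vector(labels[train])
                ),
                "test_mse": mse(
                    clf.observed_targets(Xte), targets.target_vector(labels[test])
                ),
            }
        )

    report = {
        "config": asdict(config),
        "n_subjects": int(data.n_subjects),
        "n_genes": int(data.n_genes),
        "n_features_used": int(X.shape[1]),
        "selected_indices": [int(i) for i in selected] if config.selection != "none" else None,
        "selection_note": selection_note,
        "folds": fold_reports,
        "pooled_confusion": asdict(pooled),
        "pooled_metrics": asdict(metrics(pooled)),
    }
    return report


def report_to_json(report: dict[str, Any]) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def summarize_report(report: dict[str, Any]) -> str:
    """Human-readable one-screen summary of a run_experiment report."""
    m = report["pooled_metrics"]
    cm = report["pooled_confusion"]
    lines = [
        f"classifier: {report['config']['classifier']}  "
        f"selection: {report['config']['selection']}  "
        f"features used: {report['n_features_used']}",
        f"pooled confusion  TP={cm['tp']} FN={cm['fn']} FP={cm['fp']} TN={cm['tn']}",
        (
            f"accuracy {m['accuracy']:.5f}%  precision {m['precision']:.5f}%  "
            f"recall {m['recall']:.5f}%  F1 {m['f1']:.5f}%"
        ),
        (
            f"MCC {m['mcc']:.5f}  kappa {m['kappa']:.5f}  "
            f"error rate {m['error_rate']:.5f}%"
        ),
    ]
    return "\n".join(lines)
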