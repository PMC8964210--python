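"""Metrics and the five-stage experimental protocol.

Implements confusion matrices, one-vs-rest precision/recall/F1 with macro
averaging, the normal-vs-cancerous binary collapse (accuracy, sensitivity,
specificity), Cohen's kappa, a Brier-style membership mean-squared error,
stratified 70/30 splitting, stratified k-fold cross-validation (k = 12 by
default), and the with/without-feature-selection comparison experiment.

Zero-division conventions (stated so every hand example is exact):
a class never predicted gets precision 0 and F1 0 with a warning; an
undefined binary rate (zero denominator) is reported as None; kappa with
chance agreement 1 is defined as 0 with a warning.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split

from .fcm import FCMConfig, class_memberships, fcm_predict, fit_classifier
from .synthetic import CANCEROUS_CLASSES, CLASS_NAMES, NORMAL_CLASSES

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "ExperimentConfig",
    "confusion_matrix",
    "prf",
    "binary_metrics",
    "collapse_to_binary",
    "kappa",
    "mse_metric",
    "stratified_split",
    "kfold_cv",
    "evaluate_predictions",
    "run_experiment",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = actual classes and columns = predicted classes."""

    counts: np.ndarray
    class_names: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_names", tuple(self.class_names))
        K = len(self.class_names)
        if counts.shape != (K, K):
            raise ValueError("counts must be K x K for K class names")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.counts, index=list(self.class_names), columns=list(self.class_names)
        ).to_csv(path)


def confusion_matrix(y_true, y_pred, class_names) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    class_names = tuple(class_names)
    known = set(class_names)
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        unknown = set(arr.tolist()) - known
        if unknown:
            raise ValueError(f"{name} contains labels not in class_names: {sorted(map(str, unknown))}")
    if y_true.size == 0:
        counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    else:
        counts = _sk_confusion(y_true, y_pred, labels=list(class_names))
    return ConfusionMatrix(counts=counts, class_names=class_names)


def prf(cm: ConfusionMatrix, warn: bool = True) -> dict:
    """Per-class one-vs-rest precision/recall/F1 and their macro means."""
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    pred_pos = counts.sum(axis=0)
    actual_pos = counts.sum(axis=1)

    precision = np.zeros_like(tp)
    recall = np.zeros_like(tp)
    for k in range(len(tp)):
        if pred_pos[k] == 0:
            if warn:
                warnings.warn(
                    f"class {cm.class_names[k]!r} never predicted; precision and F1 set to 0"
                )
            precision[k] = 0.0
        else:
            precision[k] = tp[k] / pred_pos[k]
        recall[k] = tp[k] / actual_pos[k] if actual_pos[k] > 0 else 0.0
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return {
        "per_class_precision": precision,
        "per_class_recall": recall,
        "per_class_f1": f1,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
    }


def binary_metrics(cm2: ConfusionMatrix) -> dict:
    """Accuracy/sensitivity/specificity/precision of a 2x2 matrix.

    Row/column order is (positive, negative).  A rate with zero denominator
    is reported as None.
    """
    counts = cm2.counts
    if counts.shape != (2, 2):
        raise ValueError("binary_metrics needs a 2 x 2 confusion matrix")
    tp, fn = int(counts[0, 0]), int(counts[0, 1])
    fp, tn = int(counts[1, 0]), int(counts[1, 1])
    total = tp + fn + fp + tn
    if total == 0:
        raise ValueError("confusion matrix is empty")

    def ratio(num: int, den: int):
        return num / den if den > 0 else None

    return {
        "accuracy": (tp + tn) / total,
        "error_rate": (fp + fn) / total,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
    }


def collapse_to_binary(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Collapse the 7-class matrix to cancerous(+) vs normal(-).

    The three squamous/columnar classes are the normal group; the four
    dysplasia grades are the cancerous (positive) group.  A cancerous cell
    predicted as any cancerous class counts as a true positive.
    """
    names = set(cm.class_names)
    unknown = names - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown classes for binary collapse: {sorted(unknown)}")
    pos = [i for i, c in enumerate(cm.class_names) if c in CANCEROUS_CLASSES]
    neg = [i for i, c in enumerate(cm.class_names) if c in NORMAL_CLASSES]
    counts = np.zeros((2, 2), dtype=np.int64)
    groups = {0: pos, 1: neg}
    for gi, rows in groups.items():
        for gj, cols in groups.items():
            counts[gi, gj] = cm.counts[np.ix_(rows, cols)].sum()
    return ConfusionMatrix(counts=counts, class_names=("cancerous", "normal"))


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa from a confusion matrix."""
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum() / total**2)
    if p_e == 1.0:
        warnings.warn("chance agreement is 1; kappa defined as 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def mse_metric(membership_rows: np.ndarray, y_true, class_names) -> float:
    """Brier-style membership error: mean of ||u_i - onehot(y_i)||^2 / K."""
    U = np.asarray(membership_rows, dtype=float)
    class_names = list(class_names)
    K = len(class_names)
    if U.shape[1] != K:
        raise ValueError("membership columns must match class_names")
    idx = {c: i for i, c in enumerate(class_names)}
    onehot = np.zeros_like(U)
    for i, y in enumerate(np.asarray(y_true)):
        onehot[i, idx[y]] = 1.0
    return float(((U - onehot) ** 2).sum(axis=1).mean() / K)


def stratified_split(labels, test_fraction: float = 0.3, seed: int = 0):
    """Seeded stratified train/test index split (disjoint, exhaustive)."""
    labels = np.asarray(labels)
    values, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        bad = values[counts < 2]
        raise ValueError(f"classes with fewer than 2 samples cannot be split: {bad.tolist()}")
    idx = np.arange(labels.size)
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=int(seed) % (2**32)
    )
    return np.sort(train), np.sort(test)


@dataclass
class EvalReport:
    """Full evaluation of one set of predictions."""

    confusion: ConfusionMatrix
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    binary: dict | None
    kappa: float
    mse: float | None
    seed: int | None = None
    config: dict | None = None

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.confusion.class_names),
            "confusion": self.confusion.counts.tolist(),
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "binary": self.binary,
            "kappa": self.kappa,
            "mse": self.mse,
            "seed": self.seed,
            "config": self.config,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_predictions(
    y_true,
    y_pred,
    class_names,
    membership_rows: np.ndarray | None = None,
    seed: int | None = None,
    config: dict | None = None,
    warn: bool = True,
) -> EvalReport:
    """Build an EvalReport; the binary collapse is included when the class
    set is the canonical seven-class taxonomy."""
    cm = confusion_matrix(y_true, y_pred, class_names)
    scores = prf(cm, warn=warn)
    accuracy = float(np.trace(cm.counts) / cm.total) if cm.total else 0.0
    binary = None
    if set(class_names) == set(CLASS_NAMES):
        binary = binary_metrics(collapse_to_binary(cm))
    mse = None
    if membership_rows is not None:
        mse = mse_metric(membership_rows, y_true, class_names)
    return EvalReport(
        confusion=cm,
        per_class_precision=scores["per_class_precision"],
        per_class_recall=scores["per_class_recall"],
        per_class_f1=scores["per_class_f1"],
        macro_precision=scores["macro_precision"],
        macro_recall=scores["macro_recall"],
        macro_f1=scores["macro_f1"],
        accuracy=accuracy,
        binary=binary,
        kappa=kappa(cm) if cm.total else 0.0,
        mse=mse,
        seed=seed,
        config=config,
    )


def kfold_cv(
    features,
    labels,
    fcm_config: FCMConfig | None = None,
    k: int = 12,
    seed: int = 0,
    subset=None,
) -> tuple[list[EvalReport], dict]:
    """Stratified k-fold cross-validation of the FCM classifier.

    ``features`` is a GroupedFeatures or a plain matrix.  If the rarest class
    has fewer than ``k`` members, ``k`` is reduced to that count with a
    warning; fewer samples than folds is an error.
    """
    from .features import GroupedFeatures

    labels = np.asarray(labels)
    if isinstance(features, GroupedFeatures):
        X = features.select(subset) if subset is not None else features.X
    else:
        X = np.asarray(features, dtype=float)
    n = labels.size
    if n < k:
        raise ValueError(f"cannot run {k}-fold CV with only {n} samples")
    min_class = int(np.unique(labels, return_counts=True)[1].min())
    if min_class < k:
        warnings.warn(f"rarest class has {min_class} samples; reducing k from {k}")
        k = min_class
    if k < 2:
        raise ValueError("need k >= 2 after stratification adjustment")
    fcm_config = fcm_config or FCMConfig()
    classes = [c for c in CLASS_NAMES if c in set(labels)] or list(np.unique(labels))
    if set(labels) - set(classes):
        classes = list(np.unique(labels))

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    reports = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in skf.split(X, labels):
            model = fit_classifier(X[tr], labels[tr], fcm_config, classes=classes)
            pred, U = fcm_predict(model, X[te])
            reports.append(
                evaluate_predictions(
                    labels[te],
                    pred,
                    classes,
                    membership_rows=class_memberships(model, U),
                    seed=seed,
                    warn=False,
                )
            )
    macro_f1 = np.array([r.macro_f1 for r in reports])
    acc = np.array([r.accuracy for r in reports])
    summary = {
        "k": k,
        "macro_f1_mean": float(macro_f1.mean()),
        "macro_f1_sd": float(macro_f1.std(ddof=1)) if k > 1 else 0.0,
        "accuracy_mean": float(acc.mean()),
        "accuracy_sd": float(acc.std(ddof=1)) if k > 1 else 0.0,
    }
    return reports, summary


@dataclass
class ExperimentConfig:
    """Configuration of the with/without-selection comparison experiment."""

    seed: int = 0
    test_fraction: float = 0.3
    selection: bool = True
    knn_baseline: bool = False
    fcm: FCMConfig = field(default_factory=FCMConfig)
    fitness_fcm: FCMConfig | None = None
    swarm: "SwarmConfig | None" = None

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "test_fraction": self.test_fraction,
            "selection": self.selection,
            "knn_baseline": self.knn_baseline,
            "fcm": dataclasses.asdict(self.fcm),
            "fitness_fcm": dataclasses.asdict(self.fitness_fcm) if self.fitness_fcm else None,
            "swarm": dataclasses.asdict(self.swarm) if self.swarm else None,
        }
        return out


def run_experiment(features, labels, config: ExperimentConfig | None = None) -> dict:
    """Run the staged protocol on an extracted feature table.

    Stage 2: one stratified 70/30 split.  Stage 3: FCM classifier on all
    features.  Stage 4 (optional): swarm feature selection on the training
    portion only, then FCM on the selected groups.  Stage 5: both models
    evaluated on the same held-out test set (plus an optional 1-NN
    baseline).  All sub-seeds derive from the master seed and are echoed in
    the report.
    """
    from .features import GroupedFeatures
    from .qgh import SwarmConfig, qgh_run

    config = config or ExperimentConfig()
    if not isinstance(features, GroupedFeatures):
        raise TypeError("run_experiment expects a GroupedFeatures")
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes")
    classes = [c for c in CLASS_NAMES if c in set(labels)]
    if set(labels) - set(classes):
        classes = list(np.unique(labels))

    master = int(config.seed)
    split_seed = int(np.random.default_rng([master, 1]).integers(2**31))
    swarm_seed = int(np.random.default_rng([master, 2]).integers(2**31))

    train_idx, test_idx = stratified_split(labels, config.test_fraction, seed=split_seed)
    report: dict = {
        "config": config.to_dict(),
        "seed": master,
        "split_seed": split_seed,
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
        "class_names": classes,
    }

    X_all = features.X
    y_tr, y_te = labels[train_idx], labels[test_idx]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model_all = fit_classifier(X_all[train_idx], y_tr, config.fcm, classes=classes)
        pred_all, U_all = fcm_predict(model_all, X_all[test_idx])
    report["without_selection"] = evaluate_predictions(
        y_te,
        pred_all,
        classes,
        membership_rows=class_memberships(model_all, U_all),
        seed=master,
        warn=False,
    ).to_dict()
    report["model_without_selection"] = model_all

    if config.selection:
        swarm = config.swarm or SwarmConfig(seed=swarm_seed)
        fitness_fcm = config.fitness_fcm or dataclasses.replace(
            config.fcm, n_init=2, max_iter=150
        )
        selection = qgh_run(features.rows(train_idx), y_tr, swarm, fitness_fcm)
        mask = np.asarray(selection.best_mask, dtype=bool)
        X_sel = features.select(mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model_sel = fit_classifier(X_sel[train_idx], y_tr, config.fcm, classes=classes)
            pred_sel, U_sel = fcm_predict(model_sel, X_sel[test_idx])
        report["selection"] = selection.to_dict()
        report["selected_mask"] = mask.astype(int).tolist()
        report["selected_groups"] = [
            n for n, m in zip(features.group_names, mask) if m
        ]
        report["with_selection"] = evaluate_predictions(
            y_te,
            pred_sel,
            classes,
            membership_rows=class_memberships(model_sel, U_sel),
            seed=master,
            warn=False,
        ).to_dict()
        report["model_with_selection"] = model_sel
    else:
        report["selection"] = None
        report["with_selection"] = None

    if config.knn_baseline:
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.preprocessing import StandardScaler

        scaler = StandardScaler().fit(X_all[train_idx])
        knn = KNeighborsClassifier(n_neighbors=1).fit(
            scaler.transform(X_all[train_idx]), y_tr
        )
        pred_knn = knn.predict(scaler.transform(X_all[test_idx]))
        report["knn_baseline"] = evaluate_predictions(
            y_te, pred_knn, classes, seed=master, warn=False
        ).to_dict()

    return report
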