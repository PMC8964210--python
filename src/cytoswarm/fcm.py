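"""Fuzzy C-means clustering used as a classifier.

The standard Bezdek alternating optimization: memberships

    u_ij = [ sum_k (d_ij / d_ik)^(2/(m-1)) ]^(-1)

(with the zero-distance row handled as a hard assignment) and centroids

    c_j = sum_i u_ij^m x_i / sum_i u_ij^m,

minimizing J = sum_ij u_ij^m ||x_i - c_j||^2.  Because FCM is unsupervised,
classification attaches a cluster -> class map learned from the training
labels (majority class of the hard-assigned points per cluster); prediction
is argmax membership followed by that map.

Features are z-scored per column with statistics stored in the model; the
raw feature space mixes pixel counts, gray levels and ratios, so Euclidean
distance is only meaningful after standardization.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FCMConfig",
    "FCMFit",
    "FCMModel",
    "fcm_memberships",
    "fcm_fit",
    "assign_cluster_labels",
    "fit_classifier",
    "fcm_predict",
    "class_memberships",
]


@dataclass
class FCMConfig:
    """Fuzzy C-means hyperparameters.

    ``n_clusters`` defaults to 7, one per morphology class; ``m`` is the
    fuzziness exponent (m -> 1 approaches hard k-means); ``tol`` is the
    absolute objective-change stopping threshold; ``n_init`` seeded restarts
    keep the best final objective.

    The default m = 1.5 sits in the common practical range (1.1-2): with
    many clusters in a moderate-dimensional standardized space, large m
    (including the textbook m = 2) makes the trivial all-centroids-at-the-
    grand-mean fixed point attracting and the clustering collapses; m = 1.5
    keeps well-separated structure stable while remaining genuinely fuzzy.
    """

    n_clusters: int = 7
    m: float = 1.5
    tol: float = 1e-5
    max_iter: int = 300
    seed: int = 0
    n_init: int = 5

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzziness m must be > 1")
        if self.tol <= 0 or self.max_iter < 1 or self.n_init < 1:
            raise ValueError("tol must be > 0, max_iter and n_init >= 1")


def fcm_memberships(X: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix U (n x C); rows sum to 1.

    A point at zero distance from a centroid gets membership 1 there (first
    such centroid) and 0 elsewhere.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    D = cdist(X, centroids)
    U = np.zeros_like(D)
    zero_rows = (D == 0).any(axis=1)
    if zero_rows.any():
        hit = np.argmax(D[zero_rows] == 0, axis=1)
        U[np.nonzero(zero_rows)[0], hit] = 1.0
    ok = ~zero_rows
    if ok.any():
        inv = D[ok] ** (-2.0 / (m - 1.0))
        U[ok] = inv / inv.sum(axis=1, keepdims=True)
    return U


@dataclass
class FCMFit:
    """Raw clustering result in standardized feature space."""

    centroids: np.ndarray
    memberships: np.ndarray
    objective_trace: list[float]
    mean: np.ndarray
    sd: np.ndarray
    config: FCMConfig


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def _single_fit(Z: np.ndarray, config: FCMConfig, restart: int) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n = Z.shape[0]
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, int(restart)])
    idx = rng.choice(n, size=config.n_clusters, replace=False)
    centroids = Z[idx].copy()
    # duplicate data points as initial centroids would break the membership
    # formula; nudge them apart
    for j in range(1, config.n_clusters):
        while np.any(np.all(np.isclose(centroids[:j], centroids[j]), axis=1)):
            centroids[j] = centroids[j] + rng.normal(0, 1e-6, size=centroids[j].shape)

    trace: list[float] = []
    U = fcm_memberships(Z, centroids, config.m)
    for _ in range(config.max_iter):
        Um = U**config.m
        weight = Um.sum(axis=0)
        new = centroids.copy()
        nonzero = weight > 0
        new[nonzero] = (Um.T[nonzero] @ Z) / weight[nonzero, None]
        centroids = new
        D2 = cdist(Z, centroids) ** 2
        J = float((Um * D2).sum())
        trace.append(J)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < config.tol:
            break
        U = fcm_memberships(Z, centroids, config.m)
    U = fcm_memberships(Z, centroids, config.m)
    return centroids, U, trace


def fcm_fit(X: np.ndarray, config: FCMConfig) -> FCMFit:
    """Fit FCM with ``n_init`` seeded restarts, keeping the best final J."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    if X.shape[0] < config.n_clusters:
        raise ValueError(
            f"need at least n_clusters={config.n_clusters} samples, got {X.shape[0]}"
        )
    mean, sd = _standardize_stats(X)
    Z = (X - mean) / sd

    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for r in range(config.n_init):
        centroids, U, trace = _single_fit(Z, config, r)
        if best is None or trace[-1] < best[2][-1]:
            best = (centroids, U, trace)
    centroids, U, trace = best
    return FCMFit(
        centroids=centroids,
        memberships=U,
        objective_trace=trace,
        mean=mean,
        sd=sd,
        config=config,
    )


def assign_cluster_labels(U: np.ndarray, y_train, classes=None) -> dict[int, object]:
    """Map each cluster to the majority class of its hard-assigned points.

    Ties break toward the class earliest in ``classes`` (sorted unique labels
    by default).  A cluster with no hard-assigned point is mapped to the
    globally most frequent class, with a warning.
    """
    U = np.asarray(U, dtype=float)
    y_train = np.asarray(y_train)
    if classes is None:
        classes = list(np.unique(y_train))
    else:
        classes = list(classes)
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[y] for y in y_train])

    global_counts = np.bincount(y_idx, minlength=len(classes))
    global_majority = int(np.argmax(global_counts))

    hard = U.argmax(axis=1)
    mapping: dict[int, object] = {}
    for j in range(U.shape[1]):
        members = y_idx[hard == j]
        if members.size == 0:
            warnings.warn(
                f"cluster {j} received no training points; mapped to the "
                f"globally most frequent class {classes[global_majority]!r}"
            )
            mapping[j] = classes[global_majority]
        else:
            counts = np.bincount(members, minlength=len(classes))
            mapping[j] = classes[int(np.argmax(counts))]  # argmax: lowest index on ties
    return mapping


@dataclass
class FCMModel:
    """A fitted FCM classifier: centroids + standardization + label map."""

    centroids: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    m: float
    cluster_to_class: dict[int, object]
    objective_trace: list[float]
    classes: list
    config: FCMConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centroids": self.centroids.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "m": self.m,
            "cluster_to_class": {str(k): v for k, v in self.cluster_to_class.items()},
            "objective_trace": list(map(float, self.objective_trace)),
            "classes": list(self.classes),
            "config": dataclasses.asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FCMModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            centroids=np.array(payload["centroids"], dtype=float),
            mean=np.array(payload["mean"], dtype=float),
            sd=np.array(payload["sd"], dtype=float),
            m=float(payload["m"]),
            cluster_to_class={int(k): v for k, v in payload["cluster_to_class"].items()},
            objective_trace=payload["objective_trace"],
            classes=payload["classes"],
            config=FCMConfig(**payload["config"]),
        )


def fit_classifier(X: np.ndarray, y, config: FCMConfig, classes=None) -> FCMModel:
    """Fit FCM on labelled data and learn the cluster -> class map."""
    fit = fcm_fit(X, config)
    mapping = assign_cluster_labels(fit.memberships, y, classes=classes)
    if classes is None:
        classes = list(np.unique(np.asarray(y)))
    return FCMModel(
        centroids=fit.centroids,
        mean=fit.mean,
        sd=fit.sd,
        m=config.m,
        cluster_to_class=mapping,
        objective_trace=fit.objective_trace,
        classes=list(classes),
        config=config,
    )


def fcm_predict(model: FCMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict class labels; returns (labels, cluster membership rows).

    Membership ties break toward the lowest cluster index (argmax rule).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        return np.array([], dtype=object), np.zeros((0, model.centroids.shape[0]))
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: model has {model.centroids.shape[1]} features, "
            f"X has {X.shape[1]}"
        )
    Z = (X - model.mean) / model.sd
    U = fcm_memberships(Z, model.centroids, model.m)
    hard = U.argmax(axis=1)
    labels = np.array([model.cluster_to_class[int(j)] for j in hard], dtype=object)
    return labels, U


def class_memberships(model: FCMModel, U: np.ndarray) -> np.ndarray:
    """Aggregate cluster memberships into per-class memberships.

    Column order follows ``model.classes``; rows remain stochastic.
    """
    U = np.asarray(U, dtype=float)
    K = len(model.classes)
    out = np.zeros((U.shape[0], K))
    idx = {c: i for i, c in enumerate(model.classes)}
    for j in range(U.shape[1]):
        out[:, idx[model.cluster_to_class[j]]] += U[:, j]
    return out
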