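"""KNN tumor/normal classification on subnetwork activity features.

A k-nearest-neighbor voter with the city-block (Manhattan) metric, k = 5 by
default, evaluated either on an independent test set or under two-level
nested cross-validation (10 stratified outer folds; within each outer
training set, 10 inner folds select k from {1, 3, 5, 7, 9} by accuracy, ties
to the smallest k). The vote fraction for the tumor class doubles as the
ranking score for a Mann–Whitney AUC — with k = 5 this is a coarse 6-level
score, which is the cost of a hard-voting classifier. Tie-breaks are fully
deterministic: neighbors sort by (distance, sample index) and a split vote
goes to the positive (tumor) class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .io_formats import NORMAL, TUMOR, SubnetmarkError

logger = logging.getLogger("subnetmark")

DEFAULT_K_GRID = (1, 3, 5, 7, 9)

__all__ = [
    "KnnConfig",
    "ClassificationReport",
    "city_block_distance",
    "knn_predict",
    "confusion_metrics",
    "roc_auc",
    "nested_cv",
    "evaluate_train_test",
    "pca_project",
]


@dataclass(frozen=True)
class KnnConfig:
    k: int = 5
    n_outer: int = 10
    n_inner: int = 10
    seed: int = 0
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    select_k: bool = True  # False: freeze k at ``k`` in nested CV

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_outer < 2 or self.n_inner < 2:
            raise SubnetmarkError("k >= 1 and n_outer, n_inner >= 2 required")
        if self.k % 2 == 0:
            warnings.warn("even k can produce split votes; odd k recommended")


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: list[list[int]]  # [[TP, FN], [FP, TN]]
    per_fold: list[dict] = field(default_factory=list)
    positive_class: str = TUMOR

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": self.confusion,
            "per_fold": self.per_fold,
            "positive_class": self.positive_class,
        }


def city_block_distance(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise SubnetmarkError("vectors differ in length")
    return float(np.abs(u - v).sum())


def knn_predict(
    train_features: np.ndarray,
    train_labels: Sequence[str],
    test_features: np.ndarray,
    k: int = 5,
) -> tuple[list[str], np.ndarray]:
    """Labels and tumor-vote fractions for each test sample.

    Neighbors are the k training samples closest in city-block distance,
    ties at the k-th neighbor broken by training-sample index after sorting
    by (distance, index); the predicted label is tumor iff the tumor vote
    fraction is >= 0.5 (a split vote goes to the positive class).
    """
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    t = np.atleast_2d(np.asarray(test_features, dtype=float))
    if k > x.shape[0]:
        raise SubnetmarkError(f"k={k} exceeds {x.shape[0]} training samples")
    if not {TUMOR, NORMAL} <= set(y.tolist()):
        raise SubnetmarkError("training labels must include both classes")
    d = cdist(t, x, metric="cityblock")
    idx = np.arange(x.shape[0])
    scores = np.empty(t.shape[0])
    labels = []
    for i in range(t.shape[0]):
        order = np.lexsort((idx, d[i]))[:k]
        votes = float(np.sum(y[order] == TUMOR))
        scores[i] = votes / k
        labels.append(TUMOR if scores[i] >= 0.5 else NORMAL)
    return labels, scores


def confusion_metrics(
    true_labels: Sequence[str], predicted: Sequence[str]
) -> tuple[list[list[int]], float, float, float]:
    """Confusion table [[TP, FN], [FP, TN]] and accuracy/sens/spec."""
    tp = sum(1 for t, p in zip(true_labels, predicted) if t == TUMOR and p == TUMOR)
    fn = sum(1 for t, p in zip(true_labels, predicted) if t == TUMOR and p == NORMAL)
    fp = sum(1 for t, p in zip(true_labels, predicted) if t == NORMAL and p == TUMOR)
    tn = sum(1 for t, p in zip(true_labels, predicted) if t == NORMAL and p == NORMAL)
    total = tp + fn + fp + tn
    acc = (tp + tn) / total if total else float("nan")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return [[tp, fn], [fp, tn]], acc, sens, spec


def roc_auc(scores: np.ndarray, labels: Sequence[str]) -> float:
    """Mann–Whitney AUC: P(score_tumor > score_normal) + 0.5 P(equal)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == TUMOR]
    neg = s[y == NORMAL]
    if pos.size == 0 or neg.size == 0:
        raise SubnetmarkError("AUC needs both classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (pos.size * neg.size))


def evaluate_train_test(
    train_features: np.ndarray,
    train_labels: Sequence[str],
    test_features: np.ndarray,
    test_labels: Sequence[str],
    k: int = 5,
) -> ClassificationReport:
    """Fit-free KNN evaluation on an independent test set."""
    pred, scores = knn_predict(train_features, train_labels, test_features, k=k)
    confusion, acc, sens, spec = confusion_metrics(test_labels, pred)
    return ClassificationReport(
        acc, sens, spec, roc_auc(scores, test_labels), confusion,
        per_fold=[{"fold": 0, "k": k, "n_test": len(pred)}],
    )


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

FeatureBuilder = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    counts = [int((labels == c).sum()) for c in np.unique(labels)]
    n = min(min(counts), n_folds)
    if n < n_folds:
        logger.warning("reducing folds %d -> %d (smallest class)", n_folds, n)
    if n < 2:
        raise SubnetmarkError("a class is too small for stratified CV")
    skf = StratifiedKFold(n_splits=n, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def _inner_select_k(x, y, config: KnnConfig, seed: int) -> int:
    grid = [k for k in config.k_grid if k <= max(2, len(y) - 1)]
    accs = {k: 0.0 for k in grid}
    counts = 0
    for tr, te in _stratified_folds(y, config.n_inner, seed):
        if len({*y[tr]}) < 2:
            continue
        counts += len(te)
        for k in grid:
            if k > len(tr):
                continue
            pred, _ = knn_predict(x[tr], y[tr], x[te], k=k)
            accs[k] += float(np.sum(np.asarray(pred) == y[te]))
    # ties toward the smallest k
    return min(grid, key=lambda k: (-accs[k], k))


def nested_cv(
    features: np.ndarray,
    labels: Sequence[str],
    config: KnnConfig | None = None,
    feature_builder: Optional[FeatureBuilder] = None,
) -> ClassificationReport:
    """Two-level nested CV with pooled outer-fold metrics.

    Outer folds are stratified; inner CV on each outer-training portion
    selects k (unless ``select_k`` is False, which freezes ``config.k``).
    ``feature_builder(train_idx, test_idx)`` lets callers recompute features
    (gene selection, directions) on the outer-training portion only so no
    evaluation sample leaks into its own feature definition; by default the
    supplied feature matrix is indexed directly.
    """
    config = config or KnnConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if set(y.tolist()) != {TUMOR, NORMAL}:
        raise SubnetmarkError("labels must be tumor/normal with both present")

    all_true: list[str] = []
    all_pred: list[str] = []
    all_scores: list[float] = []
    per_fold = []
    for fold, (tr, te) in enumerate(_stratified_folds(y, config.n_outer, config.seed)):
        if len({*y[tr]}) < 2:
            raise SubnetmarkError(f"outer fold {fold}: a class is absent from training")
        if feature_builder is not None:
            x_tr, x_te = feature_builder(tr, te)
        else:
            x_tr, x_te = x[tr], x[te]
        if config.select_k:
            k = _inner_select_k(x_tr, y[tr], config, seed=config.seed + fold + 1)
        else:
            k = config.k
        k = min(k, len(tr))
        pred, scores = knn_predict(x_tr, y[tr], x_te, k=k)
        all_true.extend(y[te].tolist())
        all_pred.extend(pred)
        all_scores.extend(scores.tolist())
        per_fold.append(
            {
                "fold": fold,
                "k": k,
                "test_indices": [int(i) for i in te],
                "train_indices": [int(i) for i in tr],
            }
        )
    confusion, acc, sens, spec = confusion_metrics(all_true, all_pred)
    auc = roc_auc(np.array(all_scores), all_true)
    return ClassificationReport(acc, sens, spec, auc, confusion, per_fold)


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------

def pca_project(
    features: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component coordinates of samples plus variance fractions.

    Features are centered internally; each component's sign is fixed so its
    largest-magnitude loading is positive. ``n_components`` beyond the matrix
    rank is truncated with a warning.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[0] < 2:
        raise SubnetmarkError("PCA needs at least 2 samples")
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    if n_components > rank:
        warnings.warn(f"n_components {n_components} > rank {rank}; truncating")
        n_components = max(rank, 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    return coords, pca.explained_variance_ratio_
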