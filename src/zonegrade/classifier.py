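"""Correlation-distance KNN with train-fitted feature normalization.

The classifier is deliberately simple: z-score each selected feature using
statistics of the training rows only, rank training samples by correlation
distance to the query, and report the fraction of positives among the k
nearest as the probability score. Five one-vs-rest binary groupings of the
ISUP Grade Groups share this classifier; the final multiclass label is the
task with the highest score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KNNConfig",
    "BinaryTask",
    "TASKS",
    "NormalizationParams",
    "fit_normalization",
    "apply_normalization",
    "correlation_distance",
    "pairwise_distances",
    "knn_score",
    "knn_score_matrix",
    "ovr_assign",
    "binarize",
]


@dataclass(frozen=True)
class KNNConfig:
    """KNN settings. Distance is fixed to correlation, normalization to
    per-feature z-scoring fitted on training samples only; only k varies."""

    k: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")


@dataclass(frozen=True)
class BinaryTask:
    """One one-vs-rest grouping of Grade Groups."""

    name: str
    positive_groups: frozenset[int]

    def labels(self, gg: np.ndarray) -> np.ndarray:
        """Binary labels (1 = positive grouping) for an array of Grade Groups."""
        return np.isin(np.asarray(gg), sorted(self.positive_groups)).astype(int)


#: the five binary models, in declared tie-break order
TASKS: tuple[BinaryTask, ...] = (
    BinaryTask("GG1_vs_rest", frozenset({1})),
    BinaryTask("GG2_vs_rest", frozenset({2})),
    BinaryTask("GG12_vs_rest", frozenset({1, 2})),
    BinaryTask("GG3_vs_rest", frozenset({3})),
    BinaryTask("GG45_vs_rest", frozenset({4, 5})),
)
TASK_BY_NAME = {t.name: t for t in TASKS}


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature mean and population SD estimated from training rows."""

    mean: np.ndarray
    sd: np.ndarray


def fit_normalization(train: np.ndarray) -> NormalizationParams:
    """Column means and population SDs of the training matrix.

    Constant columns (sd = 0) normalize to all-zero, carrying no
    information rather than blowing up.
    """
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("training matrix must be 2-D and non-empty")
    return NormalizationParams(mean=X.mean(axis=0), sd=X.std(axis=0))


def apply_normalization(X: np.ndarray, params: NormalizationParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = np.where(params.sd > 0, params.sd, 1.0)
    Z = (X - params.mean) / sd
    Z[..., params.sd == 0] = 0.0
    return Z


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson correlation across the selected features, in [0, 2].

    If either vector has zero variance the correlation is undefined and the
    distance is 1 by convention (maximally uninformative).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if u.ndim != 1 or u.size < 2:
        raise ValueError("vectors must be 1-D with length >= 2")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        return 1.0
    return float(1.0 - (uc @ vc) / (nu * nv))


def pairwise_distances(test: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Distance matrix (n_test, n_train) used by the KNN search.

    Correlation distance for >= 2 selected features. With a single feature
    every vector is constant and correlation is undefined everywhere, so
    the search degrades to absolute intensity difference, preserving the
    nearest-neighbor semantics for one-feature subsets.
    """
    test = np.atleast_2d(np.asarray(test, dtype=float))
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if test.shape[1] != train.shape[1]:
        raise ValueError("feature dimensions differ")
    if test.shape[1] < 2:
        return np.abs(test - train.T)
    tc = test - test.mean(axis=1, keepdims=True)
    rc = train - train.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(tc, axis=1)
    rn = np.linalg.norm(rc, axis=1)
    const_t = tn == 0
    const_r = rn == 0
    tc = tc / np.where(const_t, 1.0, tn)[:, None]
    rc = rc / np.where(const_r, 1.0, rn)[:, None]
    D = 1.0 - tc @ rc.T
    D[const_t, :] = 1.0
    D[:, const_r] = 1.0
    return D


def knn_score_matrix(train_X: np.ndarray, train_y: np.ndarray,
                     test_X: np.ndarray, cfg: KNNConfig) -> np.ndarray:
    """Probability scores for a batch of (already normalized) test rows.

    Score = fraction of positive labels among the k nearest training rows;
    distance ties are broken by ascending training-sample index (stable
    sort), so runs are reproducible.
    """
    train_X = np.atleast_2d(train_X)
    train_y = np.asarray(train_y)
    if cfg.k > train_X.shape[0]:
        raise ValueError(
            f"k={cfg.k} exceeds the {train_X.shape[0]} training samples")
    D = pairwise_distances(test_X, train_X)
    order = np.argsort(D, axis=1, kind="stable")
    return train_y[order[:, :cfg.k]].mean(axis=1)


def knn_score(train_X: np.ndarray, train_y: np.ndarray, x: np.ndarray,
              cfg: KNNConfig) -> float:
    """Score for a single test vector."""
    return float(knn_score_matrix(train_X, train_y,
                                  np.atleast_2d(x), cfg)[0])


def ovr_assign(scores, tasks: tuple[BinaryTask, ...] = TASKS) -> BinaryTask:
    """One-vs-rest label: the task with the highest probability score.

    Exact ties go to the earliest task in the declared order.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no scores supplied")
    if len(scores) != len(tasks):
        raise ValueError("one score per task required")
    return tasks[int(np.argmax(scores))]


def binarize(score: float, threshold: float = 0.5) -> int:
    """Threshold a probability score; the boundary counts as positive."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return int(score >= threshold)
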