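"""kNN classification of thermal feature vectors.

A k-nearest-neighbor classifier separates animal from non-animal feature
vectors and, beyond the majority-vote label, exposes the animal-vote
fraction g_A = k_A / k as a likelihood for the downstream track-belief
update. Distances are Euclidean on the raw DCT coefficients (which share
degree-Celsius-derived units); optional standardization is available but off
by default. Neighbor ties at the k-th rank are broken by training-set
insertion order so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .signatures import FeatureVector

__all__ = [
    "ThermalKNNClassifier",
    "TrainingSet",
    "KnnResult",
    "knn_classify",
    "clamp_likelihood",
    "fit_training_set",
    "FEATURE_COLUMNS",
]

ANIMAL = "animal"
NON_ANIMAL = "non_animal"

#: Canonical CSV feature-table layout (c-columns expand with n_coeff).
FEATURE_COLUMNS = ["id", "frame_index", "row", "col", "area", "M"]


def clamp_likelihood(g: float, lo: float = 0.05, hi: float = 0.95) -> float:
    """Clamp a vote fraction into [lo, hi].

    Keeps the recursive belief update away from the absorbing states 0 and
    1, so later contrary evidence can still move the belief.
    """
    return min(hi, max(lo, g))


@dataclass
class KnnResult:
    """Outcome of classifying one feature vector."""

    label: str
    g_a: float
    k_a: int
    distances: np.ndarray


class ThermalKNNClassifier(ClassifierMixin, BaseEstimator):
    """kNN classifier with a deterministic animal-vote likelihood.

    Parameters
    ----------
    k : int, default 11
        Number of neighbors in the majority vote.
    positive_label : str, default "animal"
        Class counted in the numerator of the vote fraction g_A.
    standardize : bool, default False
        Z-score features on the training set before distance computation.

    Attributes
    ----------
    X_, y_ : training data in insertion order (ties at the k-th neighbor
        rank resolve toward earlier rows).
    classes_ : the two class labels.
    class_counts_ : dict label -> training count.
    """

    def __init__(self, k: int = 11, positive_label: str = ANIMAL,
                 standardize: bool = False):
        self.k = k
        self.positive_label = positive_label
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D array")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds training size {X.shape[0]}")
        if self.positive_label not in classes:
            raise ValueError(f"positive label {self.positive_label!r} absent from y")
        self.X_ = X
        self.y_ = y
        self.classes_ = classes
        self.class_counts_ = {str(c): int((y == c).sum()) for c in classes}
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        self.n_features_in_ = X.shape[1]
        return self

    def _prep(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        if self.standardize:
            X = (X - self.mean_) / self.scale_
        return X

    def kneighbors(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Distances and training indices of the k nearest neighbors.

        Stable sort over insertion order makes exact-tie resolution
        deterministic.
        """
        check_is_fitted(self, "X_")
        X = self._prep(X)
        train = self._prep(self.X_) if self.standardize else self.X_
        d = np.sqrt(((X[:, None, :] - train[None, :, :]) ** 2).sum(axis=2))
        order = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        return np.take_along_axis(d, order, axis=1), order

    def vote_fraction(self, X) -> np.ndarray:
        """g_A = k_A / k for each row of X (unclamped)."""
        _, idx = self.kneighbors(X)
        return (self.y_[idx] == self.positive_label).mean(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        """Vote fractions per class, columns ordered as ``classes_``."""
        g = self.vote_fraction(X)
        cols = [g if c == self.positive_label else 1.0 - g for c in self.classes_]
        return np.column_stack(cols)

    def predict(self, X) -> np.ndarray:
        g = self.vote_fraction(X)
        neg = self.classes_[self.classes_ != self.positive_label][0]
        return np.where(g > 0.5, self.positive_label, neg)


@dataclass
class TrainingSet:
    """Labeled feature vectors for the kNN classifier."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        classes = np.unique(self.y)
        if classes.size < 2:
            raise ValueError("training set must contain both classes")

    @property
    def class_counts(self) -> dict[str, int]:
        return {str(c): int((self.y == c).sum()) for c in np.unique(self.y)}

    def classifier(self, k: int = 11, **kwargs) -> ThermalKNNClassifier:
        return ThermalKNNClassifier(k=k, **kwargs).fit(self.X, self.y)


def fit_training_set(table: pd.DataFrame, n_coeff: int = 7) -> TrainingSet:
    """Build a TrainingSet from a labeled feature table.

    Expects columns ``c0 ... c{n_coeff-1}`` and ``label``; duplicate rows
    are preserved (kNN voting is multiset-based).
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    cols = [f"c{i}" for i in range(n_coeff)]
    missing = [c for c in cols + ["label"] if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return TrainingSet(X=table[cols].to_numpy(float), y=table["label"].to_numpy())


def knn_classify(
    fv: FeatureVector | np.ndarray, training: TrainingSet, k: int = 11
) -> KnnResult:
    """Classify one feature vector; returns label, g_A and k_A."""
    x = fv.coefficients if isinstance(fv, FeatureVector) else np.asarray(fv, float)
    clf = training.classifier(k=k)
    dist, idx = clf.kneighbors(x[None, :])
    k_a = int((clf.y_[idx[0]] == ANIMAL).sum())
    g_a = k_a / k
    label = ANIMAL if k_a * 2 > k else NON_ANIMAL
    return KnnResult(label=label, g_a=g_a, k_a=k_a, distances=dist[0])


def features_to_table(records: list[dict], n_coeff: int = 7) -> pd.DataFrame:
    """Assemble per-blob feature records into the canonical CSV layout."""
    cols = FEATURE_COLUMNS + [f"c{i}" for i in range(n_coeff)] + ["label"]
    return pd.DataFrame(records, columns=cols)
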