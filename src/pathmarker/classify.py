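"""Nearest-neighbour classification with cosine nearness, jackknife
validation and incremental feature selection (IFS).

The nearness between two sample vectors a, b is D = 1 - a.b/(|a||b|),
i.e. one minus the cosine of their angle: 0 for identical direction, 1 for
orthogonal, up to 2 for opposite. A sample is assigned the label of the
training sample with minimal D. Jackknife (leave-one-out) accuracy is
(TP+TN)/(TP+TN+FP+FN) and is unique for a fixed dataset: there is no
randomness anywhere in this module.

IFS evaluates the nested feature sets S_1 c S_2 c ... obtained by adding
ranked features one at a time, and picks the smallest set achieving the
maximum jackknife accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .containers import ExpressionMatrix, IFSCurve, RankedFeatureTable
from .selection import MRMRSelector


@dataclass
class PredictionOutcome:
    """Per-sample jackknife predictions with confusion counts."""

    predicted: np.ndarray
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if self.tp + self.tn + self.fp + self.fn != len(self.predicted):
            raise ValueError("confusion counts must sum to the sample count")


def nna_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine nearness D = 1 - a.b/(|a||b|); smaller means more similar."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size == 0:
        raise ValueError("vectors must have equal, positive dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("nearness is undefined for a zero vector")
    return float(1.0 - a @ b / (na * nb))


def _pairwise_nearness(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """D matrix between rows of X and rows of Y."""
    nx = np.linalg.norm(X, axis=1)
    ny = np.linalg.norm(Y, axis=1)
    if np.any(nx == 0) or np.any(ny == 0):
        raise ValueError("nearness is undefined for zero-norm samples")
    return 1.0 - (X @ Y.T) / np.outer(nx, ny)


class CosineNearestNeighbor(ClassifierMixin, BaseEstimator):
    """1-nearest-neighbour classifier under the cosine nearness measure.

    Equal-nearness ties go to the training sample with the smallest index,
    so predictions are deterministic. Scale-free: multiplying all values by
    a positive constant changes nothing.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = check_array(X, dtype=float)
        D = _pairwise_nearness(X, self.X_)
        # argmin returns the first minimum: smallest training index on ties
        return self.y_[np.argmin(D, axis=1)]


def jackknife_predict(em: ExpressionMatrix,
                      feature_subset: list[str] | None = None
                      ) -> PredictionOutcome:
    """Leave-one-out nearest-neighbour prediction of every sample.

    Each sample is assigned the label of its nearest other sample over the
    restricted feature columns. Requires both classes in every training
    fold, i.e. at least two samples per class.
    """
    if feature_subset is not None:
        idx = [em.probe_ids.index(p) for p in feature_subset]
        X = em.values[:, idx]
    else:
        X = em.values
    return _jackknife_outcome(X, em.labels)


def _jackknife_outcome(X: np.ndarray, y: np.ndarray) -> PredictionOutcome:
    y = np.asarray(y)
    if len(y) < 2:
        raise ValueError("jackknife needs at least two samples")
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("a leave-one-out fold would contain one class only")
    D = _pairwise_nearness(X, X)
    np.fill_diagonal(D, np.inf)
    pred = y[np.argmin(D, axis=1)]
    return _outcome_from_predictions(pred, y)


def _outcome_from_predictions(pred: np.ndarray,
                              y: np.ndarray) -> PredictionOutcome:
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return PredictionOutcome(pred, tp, tn, fp, fn)


def accuracy(outcome: PredictionOutcome) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    total = outcome.tp + outcome.tn + outcome.fp + outcome.fn
    if total == 0:
        raise ValueError("empty prediction outcome")
    return (outcome.tp + outcome.tn) / total


def _ifs_accuracies(X: np.ndarray, y: np.ndarray, order: np.ndarray,
                    max_i: int) -> np.ndarray:
    """Jackknife accuracy for each nested prefix of ``order``.

    The Gram matrix over the first i columns is grown incrementally by the
    rank-one update of column i, so the scan costs O(max_i * n^2).
    """
    y = np.asarray(y)
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("a leave-one-out fold would contain one class only")
    n = X.shape[0]
    G = np.zeros((n, n))
    acc = np.empty(max_i)
    for i in range(max_i):
        col = X[:, order[i]]
        G += np.outer(col, col)
        sq = np.diag(G).copy()
        if np.any(sq == 0):
            raise ValueError("nearness is undefined for zero-norm samples")
        D = 1.0 - G / np.sqrt(np.outer(sq, sq))
        np.fill_diagonal(D, np.inf)
        pred = y[np.argmin(D, axis=1)]
        acc[i] = float(np.mean(pred == y))
    return acc


def ifs_scan(ranking: RankedFeatureTable, em: ExpressionMatrix,
             max_i: int | None = None) -> IFSCurve:
    """Evaluate jackknife accuracy for every prefix S_1..S_max_i of a
    ranked feature table (default max_i = min(1000, table length))."""
    if max_i is None:
        max_i = min(1000, len(ranking))
    if max_i < 1:
        raise ValueError("max_i must be at least 1")
    if max_i > len(ranking):
        raise ValueError(f"max_i = {max_i} exceeds ranking length "
                         f"{len(ranking)}")
    col_of = {p: j for j, p in enumerate(em.probe_ids)}
    order = np.array([col_of[p] for p in ranking.table["probe_id"]][:max_i],
                     dtype=np.intp)
    acc = _ifs_accuracies(em.values, em.labels, order, max_i)
    return IFSCurve(pd.DataFrame({"n_features": np.arange(1, max_i + 1),
                                  "accuracy": acc}))


def optimal_feature_set(curve: IFSCurve,
                        ranking: RankedFeatureTable) -> list[str]:
    """The prefix S_i at the smallest i achieving the curve's maximum."""
    i, _ = curve.peak()
    return ranking.top(i)


class IncrementalFeatureSelector(SelectorMixin, BaseEstimator):
    """IFS: rank features, scan nested prefixes by jackknife accuracy of the
    cosine nearest-neighbour classifier, keep the smallest best prefix.

    Parameters
    ----------
    ranker : estimator with ``ranking_`` after fit, or None
        Feature ranker; defaults to ``MRMRSelector(n_features=max_features)``.
    max_features : int, default=50
        Longest prefix evaluated (the full-scale study configuration
        evaluates 1000).

    Attributes
    ----------
    ranking_ : column indices in rank order (length max_features).
    curve_ : ndarray of jackknife accuracies for prefixes 1..max_features.
    n_features_ : smallest prefix length achieving max accuracy.
    best_accuracy_ : the maximum jackknife accuracy.
    support_ : boolean mask of the optimal feature set.
    """

    def __init__(self, ranker: BaseEstimator | None = None,
                 max_features: int = 50):
        self.ranker = ranker
        self.max_features = max_features

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.max_features < 1:
            raise ValueError("max_features must be at least 1")
        max_i = min(self.max_features, X.shape[1])
        if self.ranker is None:
            ranker = MRMRSelector(n_features=max_i)
        else:
            ranker = self.ranker
        ranker.fit(X, y)
        order = np.asarray(ranker.ranking_[:max_i], dtype=np.intp)
        acc = _ifs_accuracies(X, y, order, max_i)
        best = int(np.argmax(acc))  # first max = smallest prefix
        self.ranking_ = order
        self.curve_ = acc
        self.n_features_ = best + 1
        self.best_accuracy_ = float(acc[best])
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[: self.n_features_]] = True
        return mask

    def _more_tags(self):
        return {"requires_y": True}
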