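"""Discretized mutual information, MaxRel and mRMR feature ranking.

The mRMR (maximum relevance, minimum redundancy) criterion greedily selects
the feature g maximizing D(g, c) - R(g), where D is the mutual information
between the discretized feature and the class label and R is the mean
mutual information between g and the already-selected features. Round 1 has
an empty selected set, so it picks the MaxRel (highest-relevance) feature.

Continuous expression values are discretized per probe into three states
around the probe mean: -1 below mu - alpha*sigma, +1 above mu + alpha*sigma,
0 between. Mutual information is the plug-in estimate in bits. All ties are
broken by original column order, making every ranking deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .containers import ExpressionMatrix, RankedFeatureTable


@dataclass
class DiscreteMatrix:
    """Samples x probes ternary states with the thresholds that made them."""

    states: np.ndarray           # int8 in {-1, 0, +1}
    probe_ids: list[str]
    mu: np.ndarray               # per-probe mean
    sigma: np.ndarray            # per-probe population std (ddof=0)
    alpha: float

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]


def discretize_values(values: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Ternary-discretize each column of ``values`` at mu +/- alpha*sigma.

    Constant columns (sigma = 0) map to all-zero states.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0)
    sigma = values.std(axis=0)  # ddof=0
    lo = mu - alpha * sigma
    hi = mu + alpha * sigma
    states = np.zeros(values.shape, dtype=np.int8)
    states[values < lo] = -1
    states[values > hi] = 1
    states[:, sigma == 0] = 0
    return states


def discretize(em: ExpressionMatrix, alpha: float = 1.0) -> DiscreteMatrix:
    """Discretize an expression matrix into ternary per-probe states."""
    values = em.values
    mu = values.mean(axis=0)
    sigma = values.std(axis=0)
    states = discretize_values(values, alpha=alpha)
    return DiscreteMatrix(states, list(em.probe_ids), mu, sigma, alpha)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information between two discrete sequences, in bits.

    I(X;Y) = sum over observed cells of p(x,y) * log2[p(x,y)/(p(x)p(y))],
    with 0*log(.) taken as 0. Always >= 0 up to rounding.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    if x.size == 0:
        raise ValueError("sequences must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log2(joint[mask]
                                            / (px @ py)[mask])))
    return max(mi, 0.0)


def _mi_columns_vs(states: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MI in bits of every column of ``states`` with discrete vector ``y``.

    Vectorized over columns: states are in {-1,0,1}, y is re-coded to
    0..m-1, joint counts accumulate per (state, y) cell.
    """
    n, p = states.shape
    _, yi = np.unique(y, return_inverse=True)
    m = yi.max() + 1
    si = (states + 1).astype(np.intp)  # 0,1,2
    # counts[c, s, j]: per-column joint table
    counts = np.zeros((p, 3, m))
    cols = np.broadcast_to(np.arange(p), (n, p))
    yb = np.broadcast_to(yi[:, None], (n, p))
    np.add.at(counts, (cols.ravel(), si.ravel(), yb.ravel()), 1.0)
    joint = counts / n
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    terms[~np.isfinite(terms)] = 0.0
    return np.maximum(terms.sum(axis=(1, 2)), 0.0)


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy mRMR (or MaxRel) feature selection over discretized features.

    Parameters
    ----------
    n_features : int, default=50
        Number of selection rounds; the fitted ranking has this length.
        (The full-scale study configuration evaluates 1000 rounds.)
    alpha : float, default=1.0
        Discretization width multiplier for the mu +/- alpha*sigma cuts.
    method : {"mrmr", "maxrel"}, default="mrmr"
        "mrmr" applies the relevance-minus-redundancy criterion each round;
        "maxrel" ranks by relevance alone.

    Attributes
    ----------
    ranking_ : ndarray of column indices in selection order.
    scores_ : ndarray of criterion values at selection time (relevance for
        maxrel; D - R at the selecting round for mrmr).
    relevance_ : ndarray, MI of every feature with the label, in bits.
    n_features_in_ : int
    """

    def __init__(self, n_features: int = 50, alpha: float = 1.0,
                 method: str = "mrmr"):
        self.n_features = n_features
        self.alpha = alpha
        self.method = method

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.method not in ("mrmr", "maxrel"):
            raise ValueError(f"unknown method {self.method!r}")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        n_probes = X.shape[1]
        if not 1 <= self.n_features <= n_probes:
            raise ValueError(
                f"n_features must be in [1, {n_probes}], got {self.n_features}")
        states = discretize_values(X, alpha=self.alpha)
        relevance = _mi_columns_vs(states, y)
        self.relevance_ = relevance
        self.n_features_in_ = n_probes

        if self.method == "maxrel":
            # stable sort keeps original column order among ties
            order = np.argsort(-relevance, kind="stable")[: self.n_features]
            self.ranking_ = order
            self.scores_ = relevance[order]
            return self

        ranking: list[int] = []
        scores: list[float] = []
        red_sum = np.zeros(n_probes)
        available = np.ones(n_probes, dtype=bool)
        for _ in range(self.n_features):
            if ranking:
                crit = relevance - red_sum / len(ranking)
            else:
                crit = relevance.copy()
            crit[~available] = -np.inf
            g = int(np.argmax(crit))  # first occurrence: column-order ties
            ranking.append(g)
            scores.append(float(crit[g]))
            available[g] = False
            # accumulate MI of every remaining feature with the new pick
            red_sum += _mi_columns_vs(states, states[:, g])
        self.ranking_ = np.asarray(ranking, dtype=np.intp)
        self.scores_ = np.asarray(scores)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_] = True
        return mask

    def _more_tags(self):
        return {"requires_y": True}


def max_relevance_ranking(dm: DiscreteMatrix,
                          labels: np.ndarray) -> RankedFeatureTable:
    """Rank all probes by MI with the class label (MaxRel), descending."""
    relevance = _mi_columns_vs(dm.states, np.asarray(labels))
    order = np.argsort(-relevance, kind="stable")
    df = pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "probe_id": [dm.probe_ids[i] for i in order],
        "score": relevance[order],
    })
    return RankedFeatureTable(df, kind="MaxRel")


def mrmr_select(dm: DiscreteMatrix, labels: np.ndarray,
                n_rounds: int) -> RankedFeatureTable:
    """Greedy mRMR selection for ``n_rounds`` rounds over discrete states."""
    n_probes = dm.states.shape[1]
    if not 1 <= n_rounds <= n_probes:
        raise ValueError(f"n_rounds must be in [1, {n_probes}]")
    labels = np.asarray(labels)
    relevance = _mi_columns_vs(dm.states, labels)
    ranking: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(n_probes)
    available = np.ones(n_probes, dtype=bool)
    for _ in range(n_rounds):
        crit = (relevance - red_sum / len(ranking)) if ranking \
            else relevance.copy()
        crit[~available] = -np.inf
        g = int(np.argmax(crit))
        ranking.append(g)
        scores.append(float(crit[g]))
        available[g] = False
        red_sum += _mi_columns_vs(dm.states, dm.states[:, g])
    df = pd.DataFrame({
        "rank": np.arange(1, n_rounds + 1),
        "probe_id": [dm.probe_ids[i] for i in ranking],
        "score": scores,
    })
    return RankedFeatureTable(df, kind="mRMR")


def ttest_ranking(em: ExpressionMatrix) -> RankedFeatureTable:
    """Baseline ranking by two-sided Welch t-test p-value, ascending.

    Probes with zero variance in both classes get p = 1. Ties keep original
    column order.
    """
    pos = em.values[em.labels == 1]
    neg = em.values[em.labels == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least two samples per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
    pvals = np.asarray(pvals, dtype=float)
    pvals[~np.isfinite(pvals)] = 1.0  # zero variance in both classes
    order = np.argsort(pvals, kind="stable")
    df = pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "probe_id": [em.probe_ids[i] for i in order],
        "score": pvals[order],
    })
    return RankedFeatureTable(df, kind="t-test")
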