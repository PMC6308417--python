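"""ReliefF (classification) and RReliefF (regression) feature weighting.

Nearest-neighbor-based feature relevance: a feature is rewarded when it
separates instances with different targets that lie close together, and
penalized when it differs between close instances with the same target.
Both estimators follow the sklearn conventions (``fit``, trailing-underscore
attributes, ``get_params``/``set_params``) and are deterministic: every
instance is used as an anchor and neighbor ties break by instance order.

Feature differences are range-normalized, and neighbor search uses Manhattan
distance on the range-normalized features, so weights live in [-1, 1].
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["ReliefF", "RReliefF", "relieff_rank"]


def _prepare(X: np.ndarray):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if np.isnan(X).any():
        raise ValueError("missing values are not supported")
    rng_ = X.max(axis=0) - X.min(axis=0)
    informative = rng_ > 0
    safe_range = np.where(informative, rng_, 1.0)
    Xn = (X - X.min(axis=0)) / safe_range
    Xn[:, ~informative] = 0.0  # constant features contribute nothing
    return X, Xn, informative


def _neighbor_order(Xn: np.ndarray, i: int, candidates: np.ndarray) -> np.ndarray:
    """Candidate indices sorted by Manhattan distance to instance i (stable)."""
    d = np.abs(Xn[candidates] - Xn[i]).sum(axis=1)
    return candidates[np.argsort(d, kind="stable")]


class ReliefF(BaseEstimator):
    """ReliefF feature weights for a categorical response.

    For each anchor, the k nearest same-class hits pull weights down on
    features where they differ, and the k nearest misses of each other class
    push them up, weighted by the class prior relative to the anchor's class.

    Parameters
    ----------
    n_neighbors : k nearest hits/misses per class (truncated, with a warning,
        when a class is too small).
    """

    def __init__(self, n_neighbors: int = 10):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X, Xn, informative = _prepare(X)
        y = np.asarray(y)
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 instances")
        classes, counts = np.unique(y, return_counts=True)
        priors = {c: cnt / n for c, cnt in zip(classes, counts)}
        if self.n_neighbors >= counts.min():
            warnings.warn(
                f"k={self.n_neighbors} >= smallest class size {counts.min()}; truncating"
            )
        w = np.zeros(p)
        for i in range(n):
            same = np.where((y == y[i]) & (np.arange(n) != i))[0]
            if same.size == 0:
                continue
            k_hit = min(self.n_neighbors, same.size)
            hits = _neighbor_order(Xn, i, same)[:k_hit]
            w -= np.abs(Xn[hits] - Xn[i]).sum(axis=0) / (k_hit * n)
            for c in classes:
                if c == y[i]:
                    continue
                other = np.where(y == c)[0]
                k_miss = min(self.n_neighbors, other.size)
                misses = _neighbor_order(Xn, i, other)[:k_miss]
                factor = priors[c] / (1.0 - priors[y[i]])
                w += factor * np.abs(Xn[misses] - Xn[i]).sum(axis=0) / (k_miss * n)
        self.w_ = w
        self.informative_ = informative
        self.n_features_in_ = p
        return self


class RReliefF(BaseEstimator):
    """RReliefF feature weights for a continuous response.

    Estimates, from each anchor's k nearest neighbors, the probabilities of a
    feature differing, of the response differing, and of both, with
    rank-exponential neighbor influence ``exp(-(rank/sigma)^2)`` normalized
    per anchor; the weight contrasts P(feature differs | response differs)
    against P(feature differs | response same).
    """

    def __init__(self, n_neighbors: int = 10, sigma: float = 50.0):
        self.n_neighbors = n_neighbors
        self.sigma = sigma

    def fit(self, X, y):
        X, Xn, informative = _prepare(X)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 instances")
        y_range = y.max() - y.min()
        if y_range == 0:
            raise ValueError("response is constant")
        k = min(self.n_neighbors, n - 1)
        if self.n_neighbors > n - 1:
            warnings.warn(f"k={self.n_neighbors} > n-1; truncating to {k}")
        ranks = np.arange(1, k + 1)
        infl = np.exp(-((ranks / self.sigma) ** 2))
        infl = infl / infl.sum()

        n_dc = 0.0
        n_df = np.zeros(p)
        n_dcdf = np.zeros(p)
        all_idx = np.arange(n)
        for i in range(n):
            neigh = _neighbor_order(Xn, i, all_idx[all_idx != i])[:k]
            dy = np.abs(y[neigh] - y[i]) / y_range  # (k,)
            df = np.abs(Xn[neigh] - Xn[i])  # (k, p)
            n_dc += float(infl @ dy)
            n_df += infl @ df
            n_dcdf += (infl * dy) @ df
        if n_dc == 0 or n_dc >= n:
            raise ValueError("degenerate response differences")
        self.w_ = n_dcdf / n_dc - (n_df - n_dcdf) / (n - n_dc)
        self.informative_ = informative
        self.n_features_in_ = p
        return self


def relieff_rank(
    predictors,
    response,
    k: int = 10,
    mode: str = "classification",
    feature_names: Optional[list] = None,
):
    """Ranked (predictor, weight) list, non-increasing in weight.

    ``mode="classification"`` uses ReliefF; ``mode="regression"`` uses the
    RReliefF extension for continuous responses.
    """
    X = np.asarray(predictors, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")
    if mode == "classification":
        est = ReliefF(n_neighbors=k).fit(X, response)
    elif mode == "regression":
        est = RReliefF(n_neighbors=k).fit(X, response)
    else:
        raise ValueError("mode must be 'classification' or 'regression'")
    order = np.argsort(-est.w_, kind="stable")
    return [
        (feature_names[j], float(est.w_[j]), bool(est.informative_[j])) for j in order
    ]
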