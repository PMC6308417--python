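"""Leave-one-out linear-discriminant group classification.

Four predictor datasets are compared: (I) the 28 kinematic parameters,
(II) the 24 kinetic parameters, (III) both (52), and (IV) demographics +
both (56).  Classification is by a pooled-full-covariance linear discriminant
with empirical priors; with more predictors than training subjects the pooled
covariance is singular and a small ridge (1e-6 x mean diagonal) is added.
Features are z-scored with training-fold statistics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import LeaveOneOut
from sklearn.preprocessing import StandardScaler

from .kinematics import KINEMATIC_COLUMNS
from .kinetics import KINETIC_COLUMNS

__all__ = [
    "PooledCovarianceLDA",
    "ClassificationReport",
    "build_datasets",
    "loo_cross_validate",
    "report_metrics",
    "DATASET_IDS",
]

DATASET_IDS = ("I", "II", "III", "IV")
_EXPECTED_WIDTH = {"I": 28, "II": 24, "III": 52, "IV": 56}


class PooledCovarianceLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant with pooled full covariance and empirical priors.

    Discriminant score for class c:
    ``x' S^-1 mu_c - 0.5 mu_c' S^-1 mu_c + log pi_c``; prediction is the
    arg-max class.  A singular pooled covariance S is ridge-regularized with
    ``ridge * mean(diag(S))`` added to the diagonal (warned once per fit).
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        n, p = X.shape
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        self.priors_ = counts / n
        pooled = np.zeros((p, p))
        for c, mu in zip(self.classes_, self.means_):
            d = X[y == c] - mu
            pooled += d.T @ d
        pooled /= max(n - self.classes_.size, 1)
        try:
            # reject numerically singular matrices, not just exactly singular ones
            if np.linalg.cond(pooled) > 1e10:
                raise np.linalg.LinAlgError("ill-conditioned pooled covariance")
            inv = np.linalg.inv(pooled)
        except np.linalg.LinAlgError:
            warnings.warn("singular pooled covariance; applying ridge regularization")
            lam = self.ridge * float(np.mean(np.diag(pooled)))
            if lam <= 0:
                lam = self.ridge
            inv = np.linalg.inv(pooled + lam * np.eye(p))
        self.covariance_ = pooled
        self._inv = inv
        self._lin = inv @ self.means_.T  # (p, n_classes)
        self._const = -0.5 * np.einsum("cp,pq,cq->c", self.means_, inv, self.means_) + np.log(
            self.priors_
        )
        return self

    def decision_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self._lin + self._const

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


@dataclass
class ClassificationReport:
    dataset_id: str
    confusion: pd.DataFrame  # true x predicted counts
    accuracy_pct: float
    sensitivity_pct: float  # macro one-vs-rest recall
    specificity_pct: float  # macro one-vs-rest true-negative rate
    per_class_recall_pct: Dict[str, float]
    fold_predictions: List[str] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "dataset": self.dataset_id,
            "confusion": {
                str(t): {str(c): int(v) for c, v in row.items()}
                for t, row in self.confusion.to_dict(orient="index").items()
            },
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "per_class_recall_pct": self.per_class_recall_pct,
        }


def build_datasets(feature_table: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Predictor datasets I-IV from a subject-level feature table.

    Demographics in dataset IV are age, sex (0/1), weight and height;
    clinical covariates are never predictors (controls lack them).
    """
    from .stats import DEMOGRAPHIC_PREDICTORS, _encode

    kin = feature_table[KINEMATIC_COLUMNS]
    kit = feature_table[KINETIC_COLUMNS]
    demo = pd.DataFrame(
        {c: _encode(feature_table[c]) for c in DEMOGRAPHIC_PREDICTORS},
        index=feature_table.index,
    )
    datasets = {
        "I": kin.copy(),
        "II": kit.copy(),
        "III": pd.concat([kin, kit], axis=1),
        "IV": pd.concat([demo, kin, kit], axis=1),
    }
    for did, df in datasets.items():
        if df.shape[1] != _EXPECTED_WIDTH[did]:
            raise ValueError(f"dataset {did} has {df.shape[1]} columns, "
                             f"expected {_EXPECTED_WIDTH[did]}")
        if df.isna().any().any():
            raise ValueError(f"dataset {did} contains missing values")
    return datasets


def report_metrics(confusion: pd.DataFrame):
    """(ACC, macro SEN, macro SPE, per-class recall), all in percent."""
    cm = confusion.to_numpy(float)
    if cm.size == 0 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square and non-empty")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * np.trace(cm) / total
    recalls, tnrs = [], []
    for i in range(cm.shape[0]):
        pos = cm[i].sum()
        recalls.append(cm[i, i] / pos if pos else np.nan)
        tn = total - cm[i].sum() - cm[:, i].sum() + cm[i, i]
        neg = total - cm[i].sum()
        tnrs.append(tn / neg if neg else np.nan)
    sen = 100.0 * float(np.nanmean(recalls))
    spe = 100.0 * float(np.nanmean(tnrs))
    per_class = {
        str(lbl): 100.0 * float(r) for lbl, r in zip(confusion.index, recalls)
    }
    return acc, sen, spe, per_class


def loo_cross_validate(
    dataset: pd.DataFrame,
    labels: Sequence,
    dataset_id: str = "",
    standardize: bool = True,
    ridge: float = 1e-6,
) -> ClassificationReport:
    """Leave-one-out LDA: n folds, z-scoring fit on the training fold only."""
    X = dataset.to_numpy(float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if X.shape[0] < classes.size + 2:
        raise ValueError("too few subjects for leave-one-out classification")
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    preds: List[str] = []
    for train_idx, test_idx in LeaveOneOut().split(X):
        y_tr = y[train_idx]
        if np.unique(y_tr).size < classes.size:
            warnings.warn("a class vanished from a training fold; fold skipped")
            preds.append("")
            continue
        X_tr, X_te = X[train_idx], X[test_idx]
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
            X_tr = (X_tr - scaler.mean_) / scale
            X_te = (X_te - scaler.mean_) / scale
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # expected ridge warning when p > n
            model = PooledCovarianceLDA(ridge=ridge).fit(X_tr, y_tr)
        pred = model.predict(X_te)[0]
        preds.append(str(pred))
        cm.loc[y[test_idx][0], pred] += 1
    acc, sen, spe, per_class = report_metrics(cm)
    return ClassificationReport(
        dataset_id=dataset_id,
        confusion=cm,
        accuracy_pct=acc,
        sensitivity_pct=sen,
        specificity_pct=spe,
        per_class_recall_pct=per_class,
        fold_predictions=preds,
    )
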