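"""SVM-based cross-validated evaluation and performance metrics.

Accuracy follows the confusion-count definition
ACC = (TP + TN) / (TP + TN + FP + FN) with the methylated class as
positive; sensitivity and specificity are the class-conditional rates, and
AUC is the rank-based probability that a positive outscores a negative
(ties counted one half).  Per-fold values are averaged arithmetically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features.manifest import FAMILIES, parse_feature_name

DEFAULT_SVM_CONFIG = {"kernel": "rbf", "C": 1.0, "gamma": "scale"}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("accuracy undefined for zero total count")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN), the true-positive (methylated) detection rate."""
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined without positive instances")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP), the true-negative (unmethylated) detection rate."""
    if c.tn + c.fp == 0:
        raise ValueError("specificity undefined without negative instances")
    return c.tn / (c.tn + c.fp)


def auc(scores, labels) -> float:
    """Rank-based AUC: P(score+ > score-) with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """Per-fold and mean ACC / AUC / sensitivity / specificity."""

    fold_accuracy: list[float]
    fold_auc: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    n_folds: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.fold_auc))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.fold_sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.fold_specificity))

    def to_frame(self) -> pd.DataFrame:
        """Fold-by-fold table with a trailing Mean column."""
        cols = [f"Fold {k + 1}" for k in range(self.n_folds)] + ["Mean"]
        rows = {
            "Accuracy": self.fold_accuracy + [self.mean_accuracy],
            "AUC": self.fold_auc + [self.mean_auc],
            "Sensitivity": self.fold_sensitivity + [self.mean_sensitivity],
            "Specificity": self.fold_specificity + [self.mean_specificity],
        }
        return pd.DataFrame(rows, index=cols).T

    def to_dict(self) -> dict:
        return {
            "fold_accuracy": list(self.fold_accuracy),
            "fold_auc": list(self.fold_auc),
            "fold_sensitivity": list(self.fold_sensitivity),
            "fold_specificity": list(self.fold_specificity),
            "mean_accuracy": self.mean_accuracy,
            "mean_auc": self.mean_auc,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "n_folds": self.n_folds,
            "n_features": len(self.feature_names),
        }


def evaluate_feature_set(
    X: pd.DataFrame,
    y,
    folds: np.ndarray,
    feature_names,
    svm_config: dict | None = None,
) -> MetricsReport:
    """Cross-validated SVM metrics for a given feature subset.

    Per fold: standardize on the training split, fit the SVM, score the
    held-out validation split.  Deterministic for a fixed fold assignment.
    """
    feature_names = list(feature_names)
    if not feature_names:
        raise ValueError("empty feature set")
    missing = [f for f in feature_names if f not in X.columns]
    if missing:
        raise ValueError(f"features not in matrix: {missing[:5]}")
    cfg = dict(DEFAULT_SVM_CONFIG)
    if svm_config:
        cfg.update(svm_config)

    y = np.asarray(y)
    folds = np.asarray(folds)
    Xs = X[feature_names].to_numpy(dtype=float)
    n_folds = int(folds.max()) + 1

    accs, aucs, sens, specs = [], [], [], []
    for k in range(n_folds):
        val = folds == k
        scaler = StandardScaler().fit(Xs[~val])
        clf = SVC(**cfg, random_state=0)
        clf.fit(scaler.transform(Xs[~val]), y[~val])
        Xv = scaler.transform(Xs[val])
        pred = clf.predict(Xv)
        yv = y[val]
        c = ConfusionCounts(
            tp=int(((pred == 1) & (yv == 1)).sum()),
            fn=int(((pred == 0) & (yv == 1)).sum()),
            tn=int(((pred == 0) & (yv == 0)).sum()),
            fp=int(((pred == 1) & (yv == 0)).sum()),
        )
        accs.append(accuracy(c))
        sens.append(sensitivity(c) if (yv == 1).any() else float("nan"))
        specs.append(specificity(c) if (yv == 0).any() else float("nan"))
        if (yv == 1).any() and (yv == 0).any():
            aucs.append(auc(clf.decision_function(Xv), yv))
        else:
            aucs.append(float("nan"))

    return MetricsReport(
        fold_accuracy=accs,
        fold_auc=aucs,
        fold_sensitivity=sens,
        fold_specificity=specs,
        n_folds=n_folds,
        feature_names=feature_names,
    )


def category_distribution(feature_names) -> dict[str, float]:
    """Percentage of features per family (sums to 100)."""
    feature_names = list(feature_names)
    if not feature_names:
        raise ValueError("empty feature list")
    counts = dict.fromkeys(FAMILIES, 0)
    bad = []
    for name in feature_names:
        try:
            counts[parse_feature_name(name)["family"]] += 1
        except ValueError:
            bad.append(name)
    if bad:
        raise ValueError(f"unparseable feature names: {bad[:10]}")
    total = len(feature_names)
    return {fam: 100.0 * counts[fam] / total for fam in FAMILIES}
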