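"""Hybrid feature selection and weighting (mRMR + LASSO).

Per cross-validation fold, two selectors run on the training split:

* LASSO — an L1-penalized linear fit on standardized features; features
  with nonzero coefficients are "selected" and earn ``lasso_weight``.
* mRMR — greedy minimum-redundancy / maximum-relevance ranking (F-statistic
  relevance divided by mean absolute Pearson correlation with the already
  chosen features); the top ``mrmr_k`` earn ``mrmr_weight``.

Weights accumulate across folds into a ledger; the final feature list is
chosen by scanning the ascending grid of distinct achievable ledger values
and keeping the threshold whose candidate set maximizes mean cross-validated
SVM accuracy (ties resolved toward the larger threshold, i.e. the smaller
set).  A fixed-threshold mode applies ``weight_threshold`` directly.

The whole procedure is packaged as the scikit-learn compatible selector
:class:`HybridFeatureWeighting` (fit / transform / get_support).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .evaluate import MetricsReport, evaluate_feature_set

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable parameters of the hybrid selector (defaults are the reported
    optimal operating point: alpha 0.05, weights 2.0/1.0, threshold 3.0,
    five folds)."""

    lasso_alpha: float = 0.05
    lasso_weight: float = 2.0
    mrmr_weight: float = 1.0
    weight_threshold: float = 3.0
    n_folds: int = 5
    mrmr_k: int = 100
    seed: int = 0
    threshold_mode: str = "search"  # "search" | "fixed"
    selection_on_full_data: bool = False  # compatibility flag (leaks folds)

    def __post_init__(self):
        if self.lasso_alpha <= 0:
            raise ValueError("lasso_alpha must be > 0")
        if self.lasso_weight <= 0 or self.mrmr_weight <= 0:
            raise ValueError("selector weights must be > 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.mrmr_k < 1:
            raise ValueError("mrmr_k must be >= 1")
        if self.threshold_mode not in ("search", "fixed"):
            raise ValueError("threshold_mode must be 'search' or 'fixed'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SelectionResult:
    """Outcome of the threshold search."""

    chosen_threshold: float
    features: list[str]
    per_threshold: list[dict]  # {"threshold", "n_features", "mean_accuracy"}
    ledger: dict[str, float]
    config: SelectionConfig
    per_fold_selections: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "chosen_threshold": self.chosen_threshold,
            "features": list(self.features),
            "per_threshold": list(self.per_threshold),
            "ledger": dict(self.ledger),
            "config": self.config.to_dict(),
            "per_fold_selections": [
                {k: sorted(v) for k, v in sel.items()}
                for sel in self.per_fold_selections
            ],
        }


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(labels, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold index (0..n_folds-1) per subject, seeded."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < n_folds={n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=np.int64)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = k
    return folds


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score columns; returns the scaled matrix and the non-constant mask."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(X, dtype=float)
    Z[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    return Z, keep


def lasso_select(
    X: pd.DataFrame, y, alpha: float
) -> set[str]:
    """Features with nonzero coefficient in an L1-penalized linear fit.

    Features are standardized within the given (training) data; constant
    columns are dropped with a log entry before fitting.
    """
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    Z, keep = _standardize(Xv)
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.info("lasso_select: dropping %d constant feature(s)", len(dropped))
    model = Lasso(alpha=alpha, max_iter=50000)
    model.fit(Z[:, keep], yv)
    kept_names = [n for n, k in zip(names, keep) if k]
    return {n for n, c in zip(kept_names, model.coef_) if c != 0.0}


def mrmr_select(X: pd.DataFrame, y, k: int) -> list[str]:
    """Greedy mRMR ranking of ``k`` features.

    Relevance: one-way ANOVA F-statistic of feature vs class.  Redundancy:
    mean absolute Pearson correlation with the already selected features.
    The first pick maximizes relevance; each subsequent pick maximizes
    relevance / redundancy.  Ties break toward the earlier column.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    names = list(X.columns)
    p = len(names)
    if k > p:
        logger.warning("mrmr_select: k=%d > %d features; truncating", k, p)
        k = p
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y)

    # constant columns get relevance 0 (f_classif warns and yields NaN);
    # perfectly separating columns keep +inf and rank first
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with np.errstate(divide="ignore", invalid="ignore"):
            F, _ = f_classif(Xv, yv)
    F = np.nan_to_num(F, nan=0.0, posinf=np.inf)

    # column-standardized matrix for incremental correlation computation
    Z, keep = _standardize(Xv)
    n = Z.shape[0]

    selected: list[int] = []
    selected_set: set[int] = set()
    redundancy_sum = np.zeros(p)
    for step in range(k):
        if step == 0:
            scores = F.copy()
        else:
            mean_red = redundancy_sum / len(selected)
            mean_red = np.maximum(mean_red, 1e-12)
            scores = F / mean_red
        scores_masked = scores.copy()
        scores_masked[list(selected_set)] = -np.inf
        best = int(np.argmax(scores_masked))  # argmax ties -> earliest column
        selected.append(best)
        selected_set.add(best)
        corr = np.abs(Z.T @ Z[:, best]) / n  # |Pearson r| with new pick
        corr[~keep] = 0.0
        if not keep[best]:
            corr[:] = 0.0
        redundancy_sum += corr
    return [names[i] for i in selected]


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------

def accumulate_weights(
    per_fold_selections: list[dict], config: SelectionConfig
) -> dict[str, float]:
    """Additive weight ledger over folds and selectors.

    ``per_fold_selections[k]`` maps selector name ("lasso" / "mrmr") to the
    collection of features it chose in fold k.
    """
    weights = {"lasso": config.lasso_weight, "mrmr": config.mrmr_weight}
    ledger: dict[str, float] = {}
    for fold_sel in per_fold_selections:
        for selector, feats in fold_sel.items():
            w = weights[selector]
            for f in feats:
                ledger[f] = ledger.get(f, 0.0) + w
    return ledger


def threshold_search(
    X: pd.DataFrame,
    y,
    folds: np.ndarray,
    ledger: dict[str, float],
    config: SelectionConfig,
    svm_config: dict | None = None,
) -> SelectionResult:
    """Scan distinct ledger values ascending; keep the accuracy-maximizing
    threshold (ties toward the larger threshold / smaller feature set)."""
    if not ledger:
        raise ValueError("empty weight ledger")
    manifest_order = {name: i for i, name in enumerate(X.columns)}
    thresholds = sorted(set(ledger.values()))
    per_threshold = []
    best = None
    for w in thresholds:
        feats = sorted(
            (f for f, wt in ledger.items() if wt >= w),
            key=manifest_order.__getitem__,
        )
        if not feats:
            logger.info("threshold %.3g: empty candidate set, skipped", w)
            continue
        report = evaluate_feature_set(X, y, folds, feats, svm_config)
        acc = report.mean_accuracy
        per_threshold.append(
            {"threshold": w, "n_features": len(feats), "mean_accuracy": acc}
        )
        if best is None or acc >= best[0]:  # >= : ties -> larger threshold
            best = (acc, w, feats)
    if best is None:
        raise ValueError("no non-empty candidate set at any threshold")
    _, w_star, feats_star = best
    return SelectionResult(
        chosen_threshold=w_star,
        features=feats_star,
        per_threshold=per_threshold,
        ledger=dict(ledger),
        config=config,
    )


def run_pipeline(
    X: pd.DataFrame,
    y,
    config: SelectionConfig | None = None,
    svm_config: dict | None = None,
) -> tuple[SelectionResult, MetricsReport]:
    """Full hybrid FS/FW pipeline on a cohort feature table.

    Selectors run on each fold's training split only (unless the
    ``selection_on_full_data`` compatibility flag is set); the ledger is
    thresholded and the final list evaluated on the same fold assignment.
    """
    config = config or SelectionConfig()
    y = pd.Series(np.asarray(y), index=X.index)
    if X.columns.duplicated().any():
        raise ValueError("duplicate feature names")
    folds = make_folds(y, config.n_folds, config.seed)

    per_fold: list[dict] = []
    for kf in range(config.n_folds):
        if config.selection_on_full_data:
            X_tr, y_tr = X, y
        else:
            train = folds != kf
            X_tr, y_tr = X.loc[train], y.loc[train]
        sel_lasso = lasso_select(X_tr, y_tr, config.lasso_alpha)
        sel_mrmr = set(mrmr_select(X_tr, y_tr, config.mrmr_k))
        per_fold.append({"lasso": sel_lasso, "mrmr": sel_mrmr})
        logger.info(
            "fold %d: lasso selected %d, mrmr selected %d",
            kf,
            len(sel_lasso),
            len(sel_mrmr),
        )

    ledger = accumulate_weights(per_fold, config)

    if config.threshold_mode == "fixed":
        manifest_order = {name: i for i, name in enumerate(X.columns)}
        feats = sorted(
            (f for f, wt in ledger.items() if wt >= config.weight_threshold),
            key=manifest_order.__getitem__,
        )
        if not feats:
            raise ValueError(
                f"no feature reaches fixed weight threshold {config.weight_threshold}"
            )
        result = SelectionResult(
            chosen_threshold=config.weight_threshold,
            features=feats,
            per_threshold=[],
            ledger=dict(ledger),
            config=config,
        )
    else:
        result = threshold_search(X, y, folds, ledger, config, svm_config)
    result.per_fold_selections = per_fold

    report = evaluate_feature_set(X, y, folds, result.features, svm_config)
    return result, report


def nested_evaluation(
    X: pd.DataFrame,
    y,
    config: SelectionConfig | None = None,
    svm_config: dict | None = None,
    outer_n_folds: int | None = None,
    outer_seed: int | None = None,
) -> MetricsReport:
    """Honest generalization estimate of the whole FS/FW procedure.

    The in-fold metrics returned by :func:`run_pipeline` reuse, for
    evaluation, folds that already informed the weight ledger and the
    threshold choice, so they are optimistically biased (most visibly on
    signal-free data).  Here the entire pipeline — selection, weighting,
    thresholding, and the final SVM — is refit on each outer training split
    and scored only on the held-out outer split, which makes the estimate
    unbiased at the cost of ``outer_n_folds`` pipeline fits.
    """
    from .evaluate import (
        ConfusionCounts,
        accuracy as _acc,
        auc as _auc,
        sensitivity as _sens,
        specificity as _spec,
    )
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from .evaluate import DEFAULT_SVM_CONFIG

    config = config or SelectionConfig()
    outer_n_folds = outer_n_folds or config.n_folds
    outer_seed = config.seed + 1 if outer_seed is None else outer_seed
    y = pd.Series(np.asarray(y), index=X.index)
    outer = make_folds(y, outer_n_folds, outer_seed)
    cfg = dict(DEFAULT_SVM_CONFIG)
    if svm_config:
        cfg.update(svm_config)

    accs, aucs, sens, specs = [], [], [], []
    all_features: list[str] = []
    for k in range(outer_n_folds):
        tr = outer != k
        X_tr, y_tr = X.loc[tr], y.loc[tr]
        result, _ = run_pipeline(X_tr, y_tr, config, svm_config)
        feats = result.features
        all_features.extend(f for f in feats if f not in all_features)
        scaler = StandardScaler().fit(X_tr[feats])
        clf = SVC(**cfg, random_state=0)
        clf.fit(scaler.transform(X_tr[feats]), y_tr)
        Xv = scaler.transform(X.loc[~tr, feats])
        yv = y[~tr].to_numpy()
        pred = clf.predict(Xv)
        c = ConfusionCounts(
            tp=int(((pred == 1) & (yv == 1)).sum()),
            fn=int(((pred == 0) & (yv == 1)).sum()),
            tn=int(((pred == 0) & (yv == 0)).sum()),
            fp=int(((pred == 1) & (yv == 0)).sum()),
        )
        accs.append(_acc(c))
        sens.append(_sens(c) if (yv == 1).any() else float("nan"))
        specs.append(_spec(c) if (yv == 0).any() else float("nan"))
        if (yv == 1).any() and (yv == 0).any():
            aucs.append(_auc(clf.decision_function(Xv), yv))
        else:
            aucs.append(float("nan"))

    return MetricsReport(
        fold_accuracy=accs,
        fold_auc=aucs,
        fold_sensitivity=sens,
        fold_specificity=specs,
        n_folds=outer_n_folds,
        feature_names=all_features,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator surface
# ---------------------------------------------------------------------------

class HybridFeatureWeighting(SelectorMixin, BaseEstimator):
    """Scikit-learn selector wrapping the hybrid FS/FW pipeline.

    Parameters mirror :class:`SelectionConfig`.  After ``fit``, the chosen
    features are available as ``selected_features_`` and via
    ``get_support``/``transform``; the weight ledger and the per-threshold
    accuracy trace are exposed as fitted attributes.

    Examples
    --------
    >>> from gliorad.phantom import TabularSpec, simulate_feature_matrix
    >>> ds = simulate_feature_matrix(TabularSpec(seed=1))
    >>> sel = HybridFeatureWeighting(seed=1).fit(ds.X, ds.y)
    >>> X_red = sel.transform(ds.X)
    """

    def __init__(
        self,
        lasso_alpha: float = 0.05,
        lasso_weight: float = 2.0,
        mrmr_weight: float = 1.0,
        weight_threshold: float = 3.0,
        n_folds: int = 5,
        mrmr_k: int = 100,
        seed: int = 0,
        threshold_mode: str = "search",
        selection_on_full_data: bool = False,
        svm_config: dict | None = None,
    ):
        self.lasso_alpha = lasso_alpha
        self.lasso_weight = lasso_weight
        self.mrmr_weight = mrmr_weight
        self.weight_threshold = weight_threshold
        self.n_folds = n_folds
        self.mrmr_k = mrmr_k
        self.seed = seed
        self.threshold_mode = threshold_mode
        self.selection_on_full_data = selection_on_full_data
        self.svm_config = svm_config

    def _config(self) -> SelectionConfig:
        return SelectionConfig(
            lasso_alpha=self.lasso_alpha,
            lasso_weight=self.lasso_weight,
            mrmr_weight=self.mrmr_weight,
            weight_threshold=self.weight_threshold,
            n_folds=self.n_folds,
            mrmr_k=self.mrmr_k,
            seed=self.seed,
            threshold_mode=self.threshold_mode,
            selection_on_full_data=self.selection_on_full_data,
        )

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            Xdf = X
        else:
            X = np.asarray(X, dtype=float)
            Xdf = pd.DataFrame(X, columns=[f"F{j + 1:04d}" for j in range(X.shape[1])])
        y = np.asarray(y)
        if Xdf.isna().any().any():
            raise ValueError("X contains missing values")
        result, report = run_pipeline(Xdf, y, self._config(), self.svm_config)
        self.n_features_in_ = Xdf.shape[1]
        self.feature_names_in_ = np.asarray(Xdf.columns, dtype=object)
        self.result_ = result
        self.report_ = report
        self.ledger_ = result.ledger
        self.selected_features_ = list(result.features)
        chosen = set(result.features)
        self.support_ = np.array([c in chosen for c in Xdf.columns])
        self.chosen_threshold_ = result.chosen_threshold
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
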