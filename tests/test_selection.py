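"""Hybrid feature selection and weighting: folds, LASSO, mRMR, the weight
ledger, threshold search and the sklearn estimator surface."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import hadamard
from scipy.stats import f_oneway

from gliorad import (
    HybridFeatureWeighting,
    SelectionConfig,
    TabularSpec,
    accumulate_weights,
    lasso_select,
    make_folds,
    mrmr_select,
    run_pipeline,
    simulate_feature_matrix,
    threshold_search,
)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def test_balanced_ten_subjects_five_folds():
    y = np.array([0, 1] * 5)
    folds = make_folds(y, 5, seed=0)
    for k in range(5):
        sel = y[folds == k]
        assert len(sel) == 2 and sel.sum() == 1


def test_folds_deterministic_under_seed():
    y = np.array([0] * 20 + [1] * 30)
    np.testing.assert_array_equal(make_folds(y, 5, 3), make_folds(y, 5, 3))


def test_cohort_146_fold_sizes():
    y = np.array([1] * 97 + [0] * 49)
    folds = make_folds(y, 5, 0)
    sizes = sorted(np.bincount(folds), reverse=True)
    assert sizes == [30, 29, 29, 29, 29]
    # stratification within +-1 of perfect
    for k in range(5):
        pos = y[folds == k].sum()
        assert abs(pos - 97 / 5) < 1.0


def test_folds_require_enough_class_members():
    y = np.array([0] * 3 + [1] * 20)
    with pytest.raises(ValueError, match="n_folds"):
        make_folds(y, 5, 0)


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

def test_huge_alpha_shrinks_everything():
    ds = simulate_feature_matrix(TabularSpec(seed=0))
    assert lasso_select(ds.X, ds.y, alpha=1e6) == set()


def test_orthonormal_design_soft_threshold():
    """On an orthogonal +-1 design the LASSO solution is the soft threshold
    of the univariate coefficients: only the single loaded feature (with
    coefficient magnitude > alpha) survives."""
    H = hadamard(8).astype(float)
    X = pd.DataFrame(H[:, 1:], columns=[f"F{j}" for j in range(7)])
    c = 0.3
    y = c * X["F2"].to_numpy()
    selected = lasso_select(X, y, alpha=0.05)
    assert selected == {"F2"}
    # alpha above |c| removes it
    assert lasso_select(X, y, alpha=0.4) == set()


def _coordinate_descent_lasso(X, y, alpha, n_iter=400):
    """Independent LASSO oracle: cyclic coordinate descent on standardized
    columns, objective 1/(2n)||y - Xb||^2 + alpha ||b||_1."""
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    n, p = Z.shape
    b = np.zeros(p)
    r = y - Z @ b
    for _ in range(n_iter):
        for j in range(p):
            rho = Z[:, j] @ (r + Z[:, j] * b[j]) / n
            zjj = Z[:, j] @ Z[:, j] / n
            new = np.sign(rho) * max(abs(rho) - alpha, 0.0) / zjj
            r += Z[:, j] * (b[j] - new)
            b[j] = new
    return b


def test_lasso_matches_coordinate_descent_oracle():
    ds = simulate_feature_matrix(
        TabularSpec(n_subjects=200, n_features=30, n_informative=5, seed=12)
    )
    got = lasso_select(ds.X, ds.y, alpha=0.05)
    b = _coordinate_descent_lasso(
        ds.X.to_numpy(), ds.y.to_numpy().astype(float), 0.05
    )
    want = {name for name, coef in zip(ds.X.columns, b) if abs(coef) > 1e-8}
    assert got == want
    assert set(ds.informative) <= got


def test_constant_columns_dropped_not_fatal():
    ds = simulate_feature_matrix(TabularSpec(n_features=10, seed=1))
    X = ds.X.copy()
    X["F0010"] = 1.0
    selected = lasso_select(X, ds.y, alpha=0.05)
    assert "F0010" not in selected


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def test_label_copy_ranks_first():
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * 50)
    X = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("ABCDE"))
    X["D"] = y.astype(float)
    assert mrmr_select(X, y, 3)[0] == "D"


def test_duplicate_top_feature_penalized():
    # "other" shares the class signal but has anti-correlated noise, so it
    # is nearly uncorrelated with "top"; the exact duplicate has |r| = 1
    # and its relevance/redundancy quotient loses despite equal relevance.
    rng = np.random.default_rng(1)
    y = np.array([0, 1] * 50)
    e = rng.normal(0, 0.5, 100)
    X = pd.DataFrame(
        {
            "top": y + e,
            "copy": y + e,
            "other": y - e,
            "noise1": rng.normal(size=100),
            "noise2": rng.normal(size=100),
        }
    )
    order = mrmr_select(X, y, 3)
    assert order[1] != "copy"  # redundancy quotient demotes the duplicate
    assert order == _oracle_mrmr(X, y, 3)


def _oracle_mrmr(X, y, k):
    """Exhaustive greedy oracle using scipy's F statistic and np.corrcoef."""
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    F = []
    for j in range(Xv.shape[1]):
        groups = [Xv[y == c, j] for c in np.unique(y)]
        stat, _ = f_oneway(*groups)
        F.append(0.0 if np.isnan(stat) else float(stat))
    selected = []
    remaining = list(range(len(names)))
    while len(selected) < k and remaining:
        best, best_score = None, -np.inf
        for j in remaining:
            if not selected:
                score = F[j]
            else:
                reds = []
                for s in selected:
                    with np.errstate(invalid="ignore"):
                        r = np.corrcoef(Xv[:, j], Xv[:, s])[0, 1]
                    reds.append(abs(r) if np.isfinite(r) else 0.0)
                score = F[j] / max(np.mean(reds), 1e-12)
            if score > best_score:
                best, best_score = j, score
        selected.append(best)
        remaining.remove(best)
    return [names[j] for j in selected]


def test_mrmr_matches_exhaustive_greedy_oracle():
    ds = simulate_feature_matrix(
        TabularSpec(n_subjects=80, n_features=10, n_informative=3,
                    effect_size=1.0, seed=4)
    )
    got = mrmr_select(ds.X, ds.y, 6)
    want = _oracle_mrmr(ds.X, ds.y.to_numpy(), 6)
    assert got == want


def test_k_equal_feature_count_is_permutation():
    ds = simulate_feature_matrix(TabularSpec(n_features=12, seed=6))
    order = mrmr_select(ds.X, ds.y, 12)
    assert sorted(order) == sorted(ds.X.columns)


def test_k_larger_than_feature_count_truncates():
    ds = simulate_feature_matrix(TabularSpec(n_features=8, seed=6))
    assert len(mrmr_select(ds.X, ds.y, 100)) == 8


# ---------------------------------------------------------------------------
# ledger algebra
# ---------------------------------------------------------------------------

def test_ledger_arithmetic_on_default_coefficients():
    config = SelectionConfig()
    sels = [
        {"lasso": {"a"}, "mrmr": {"a", "b"}},
        {"lasso": {"a"}, "mrmr": set()},
        {"lasso": set(), "mrmr": {"b"}},
        {"lasso": set(), "mrmr": set()},
        {"lasso": set(), "mrmr": set()},
    ]
    ledger = accumulate_weights(sels, config)
    assert ledger["a"] == pytest.approx(2.0 + 1.0 + 2.0)  # LASSO x2 + mRMR x1
    assert ledger["b"] == pytest.approx(2.0)  # mRMR only, 2 folds < threshold 3
    full = [{"lasso": {"f"}, "mrmr": {"f"}} for _ in range(5)]
    assert accumulate_weights(full, config)["f"] == pytest.approx(15.0)


@given(
    st.lists(
        st.fixed_dictionaries(
            {
                "lasso": st.sets(st.sampled_from("abcdefgh")),
                "mrmr": st.sets(st.sampled_from("abcdefgh")),
            }
        ),
        min_size=5,
        max_size=5,
    )
)
def test_ledger_bound_and_weight_lattice(sels):
    """Every weight lies in [0, n_folds*(w_l + w_m)] and is a non-negative
    integer combination of the two coefficients."""
    config = SelectionConfig()
    ledger = accumulate_weights(sels, config)
    for w in ledger.values():
        assert 0 < w <= 5 * (2.0 + 1.0)
        found = any(
            abs(w - (a * 2.0 + b * 1.0)) < 1e-12
            for a in range(6)
            for b in range(6)
        )
        assert found


@given(
    st.lists(
        st.fixed_dictionaries(
            {
                "lasso": st.sets(st.sampled_from("abcdefgh")),
                "mrmr": st.sets(st.sampled_from("abcdefgh")),
            }
        ),
        min_size=5,
        max_size=5,
    )
)
def test_candidate_sets_nested_in_threshold(sels):
    config = SelectionConfig()
    ledger = accumulate_weights(sels, config)
    thresholds = sorted(set(ledger.values()))
    prev = None
    for w in thresholds:
        cur = {f for f, wt in ledger.items() if wt >= w}
        if prev is not None:
            assert cur <= prev
        prev = cur


# ---------------------------------------------------------------------------
# threshold search and full pipeline
# ---------------------------------------------------------------------------

def test_single_weight_value_is_chosen(planted_dataset):
    ds = planted_dataset
    folds = make_folds(ds.y, 5, 0)
    ledger = {c: 3.0 for c in ds.X.columns[:10]}
    res = threshold_search(ds.X, ds.y, folds, ledger, SelectionConfig())
    assert res.chosen_threshold == 3.0
    assert len(res.features) == 10


def test_empty_ledger_rejected(planted_dataset):
    ds = planted_dataset
    folds = make_folds(ds.y, 5, 0)
    with pytest.raises(ValueError, match="ledger"):
        threshold_search(ds.X, ds.y, folds, {}, SelectionConfig())


def test_pipeline_defaults_match_reported_operating_point():
    cfg = SelectionConfig()
    assert (cfg.lasso_alpha, cfg.lasso_weight, cfg.mrmr_weight,
            cfg.weight_threshold, cfg.n_folds) == (0.05, 2.0, 1.0, 3.0, 5)


def test_pipeline_deterministic(planted_dataset):
    ds = planted_dataset
    r1, m1 = run_pipeline(ds.X, ds.y, SelectionConfig(seed=5))
    r2, m2 = run_pipeline(ds.X, ds.y, SelectionConfig(seed=5))
    assert r1.features == r2.features
    assert r1.chosen_threshold == r2.chosen_threshold
    assert m1.fold_accuracy == m2.fold_accuracy


def test_final_features_were_selected_somewhere(planted_dataset):
    ds = planted_dataset
    res, _ = run_pipeline(ds.X, ds.y, SelectionConfig(seed=2))
    union = set()
    for sel in res.per_fold_selections:
        union |= sel["lasso"] | sel["mrmr"]
    assert set(res.features) <= union


def test_fixed_threshold_mode(planted_dataset):
    ds = planted_dataset
    cfg = SelectionConfig(threshold_mode="fixed", weight_threshold=3.0, seed=2)
    res, _ = run_pipeline(ds.X, ds.y, cfg)
    assert res.chosen_threshold == 3.0
    assert all(res.ledger[f] >= 3.0 for f in res.features)


def test_duplicate_feature_names_rejected(planted_dataset):
    ds = planted_dataset
    X = ds.X.copy()
    X.columns = ["DUP"] * 2 + list(X.columns[2:])
    with pytest.raises(ValueError, match="duplicate"):
        run_pipeline(X, ds.y, SelectionConfig())


# ---------------------------------------------------------------------------
# sklearn estimator surface
# ---------------------------------------------------------------------------

def test_estimator_fit_transform_roundtrip(planted_dataset):
    ds = planted_dataset
    sel = HybridFeatureWeighting(seed=42).fit(ds.X, ds.y)
    Xr = sel.transform(ds.X)
    assert Xr.shape == (len(ds.X), len(sel.selected_features_))
    assert sel.support_.sum() == len(sel.selected_features_)
    assert sel.get_support().dtype == bool


def test_estimator_get_set_params_clone():
    from sklearn.base import clone

    sel = HybridFeatureWeighting(lasso_alpha=0.1, mrmr_k=20)
    params = sel.get_params()
    assert params["lasso_alpha"] == 0.1
    cloned = clone(sel)
    assert cloned.get_params() == params


def test_estimator_in_sklearn_pipeline(planted_dataset):
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    ds = planted_dataset
    pipe = Pipeline(
        [
            ("select", HybridFeatureWeighting(seed=0)),
            ("scale", StandardScaler()),
            ("svm", SVC()),
        ]
    )
    pipe.fit(ds.X, ds.y)
    assert pipe.score(ds.X, ds.y) > 0.9
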