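"""Pruning, standardization, tuning, LOSO evaluation, metrics, importance."""

import numpy as np
import pandas as pd
import pytest

from oracles import oracle_correlation_prune
from throwsense.errors import ContractError
from throwsense.modeling import (
    ModelSpec,
    class_metrics,
    correlation_prune,
    loso_evaluate,
    make_estimator,
    permutation_importance,
    reg_metrics,
    standardize_apply,
    standardize_fit,
    tune,
)


def _fm(X, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


# ---------------------------------------------------------------------------
# correlation pruning


def test_prune_removes_one_of_identical_pair():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 5))
    X[:, 3] = X[:, 1]  # identical copy
    res = correlation_prune(_fm(X), cutoff=0.95)
    assert sorted(res.removed) == ["f3"]  # later column drops on the tie
    assert len(res.retained) == 4


def test_prune_keeps_near_orthogonal_features():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 6))
    res = correlation_prune(_fm(X), cutoff=0.95)
    assert res.removed == {}
    assert len(res.retained) == 6


def test_prune_constant_column_flagged_not_removed():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(50, 4))
    X[:, 2] = 3.14
    res = correlation_prune(_fm(X), cutoff=0.95)
    assert "f2" in res.constant_flagged
    assert "f2" in res.retained


def test_prune_matches_independent_greedy_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n, p = 40, 8
        X = rng.normal(size=(n, p))
        # plant correlation structure
        for j in range(1, p, 2):
            X[:, j] = X[:, j - 1] + rng.uniform(0.0, 0.5) * rng.normal(size=n)
        names = [f"f{i}" for i in range(p)]
        res = correlation_prune(_fm(X, names), cutoff=0.95)
        assert res.retained == oracle_correlation_prune(X, names, 0.95)
        R = np.corrcoef(X[:, [names.index(k) for k in res.retained]], rowvar=False)
        np.fill_diagonal(R, 0.0)
        assert np.abs(R).max() <= 0.95


# ---------------------------------------------------------------------------
# standardization


def test_standardize_train_is_zero_mean_unit_sd():
    rng = np.random.default_rng(4)
    fm = _fm(rng.normal(3.0, 2.0, size=(40, 3)))
    params = standardize_fit(fm)
    Z = standardize_apply(params, fm)
    assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-9)


def test_standardize_constant_column_scale_one():
    fm = _fm(np.column_stack([np.ones(10) * 5.0, np.arange(10.0)]))
    params = standardize_fit(fm)
    assert params.zero_sd_columns == ["f0"]
    Z = standardize_apply(params, fm)
    assert np.allclose(Z[:, 0], 0.0)


def test_standardize_heldout_uses_train_params():
    train = _fm(np.array([[0.0, 10.0], [2.0, 14.0], [4.0, 18.0]]))
    test = _fm(np.array([[6.0, 10.0]]))
    params = standardize_fit(train)
    Z = standardize_apply(params, test)
    # hand arithmetic: means (2, 14), sds (2, 4)
    assert np.allclose(Z, [[(6 - 2) / 2.0, (10 - 14) / 4.0]])


def test_standardize_missing_column_error():
    params = standardize_fit(_fm(np.ones((5, 2)) * np.arange(5)[:, None]))
    with pytest.raises(ContractError):
        standardize_apply(params, pd.DataFrame({"f0": [1.0]}))


# ---------------------------------------------------------------------------
# metrics


def test_class_metrics_confusion_arithmetic():
    truth = ["pos"] * 100 + ["neg"] * 100
    pred = ["pos"] * 89 + ["neg"] * 11 + ["pos"] * 25 + ["neg"] * 75
    m = class_metrics(truth, pred)["pos"]
    assert m["sensitivity"] == pytest.approx(0.89)
    assert m["specificity"] == pytest.approx(0.75)
    assert m["balanced_accuracy"] == pytest.approx(0.82)


def test_class_metrics_perfect_predictions():
    truth = ["a", "b", "c", "a", "b", "c"]
    m = class_metrics(truth, truth)
    for cls in "abc":
        assert all(m[cls][k] == 1.0 for k in
                   ("sensitivity", "specificity", "balanced_accuracy", "f1"))


def test_class_metrics_balanced_accuracy_identity():
    rng = np.random.default_rng(5)
    truth = rng.choice(["a", "b", "c"], size=200)
    pred = rng.choice(["a", "b", "c"], size=200)
    for m in class_metrics(truth, pred).values():
        assert m["balanced_accuracy"] == pytest.approx(
            (m["sensitivity"] + m["specificity"]) / 2
        )


def test_class_metrics_empty_class_flagged():
    m = class_metrics(["a", "a"], ["a", "b"], classes=["a", "b"])
    assert m["b"].get("undefined") is True


def test_reg_metrics_hand_arithmetic():
    m = reg_metrics([20.0, 20.0], [21.0, 19.0])
    assert m["mae"] == pytest.approx(1.0)
    assert m["rmse"] == pytest.approx(1.0)
    assert m["mape"] == pytest.approx(5.0)
    z = reg_metrics([1.0, 2.0], [1.0, 2.0])
    assert (z["mae"], z["rmse"], z["mape"]) == (0.0, 0.0, 0.0)


def test_rmse_never_below_mae():
    rng = np.random.default_rng(6)
    for _ in range(10):
        t = rng.uniform(10, 30, size=50)
        p = t + rng.normal(0, 2, size=50)
        m = reg_metrics(t, p)
        assert m["rmse"] >= m["mae"] - 1e-12


# ---------------------------------------------------------------------------
# tuning


def test_tune_single_point_grid_shortcut():
    spec = ModelSpec("SVM_L", "classify_windup", grid={"C": [1.0]}, seed=0)
    assert tune(spec, np.zeros((4, 2)), np.array(["a", "a", "b", "b"])) == {"C": 1.0}


def test_tune_prefers_fitting_capacity():
    # SVR with a vanishing cost collapses to a near-constant predictor,
    # so the richer grid point must win on strongly linear data.
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 3))
    y = 21.0 + 3.0 * X[:, 0]
    spec = ModelSpec("SVM_L", "regress_velocity", grid={"C": [1e-8, 10.0]},
                     tuning_folds=5, seed=1)
    assert tune(spec, X, y) == {"C": 10.0}


def test_tune_deterministic_given_seed():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(50, 4))
    y = rng.uniform(15, 25, size=50)
    spec = ModelSpec("GBM", "regress_velocity",
                     grid={"n_estimators": [20], "max_depth": [1, 2], "learning_rate": [0.1]},
                     tuning_folds=5, seed=3)
    assert tune(spec, X, y) == tune(spec, X, y)


# ---------------------------------------------------------------------------
# LOSO evaluation


def _toy_study(n_subj=3, n_per=20, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        y = np.array(["circle", "whip"] * (n_per // 2))
        X = rng.normal(size=(n_per, 4))
        if informative:
            X[:, 0] += np.where(y == "circle", 5.0, -5.0)
        for i in range(n_per):
            rows.append({"subject_id": f"S{s}", "windup": y[i],
                         **{f"f{j}": X[i, j] for j in range(4)}})
    return pd.DataFrame(rows)


def test_loso_each_subject_predicted_exactly_once():
    fm = _toy_study()
    spec = ModelSpec("SVM_L", "classify_windup", grid={"C": [1.0]}, seed=0)
    res = loso_evaluate(spec, fm)
    counts = res.predictions.groupby("subject_id").size()
    assert sorted(counts.index) == ["S0", "S1", "S2"]
    assert (counts == 20).all()
    assert len(res.fold_info) == 3


def test_loso_separable_data_is_perfect():
    fm = _toy_study()
    spec = ModelSpec("SVM_L", "classify_windup", grid={"C": [1.0]}, seed=0)
    res = loso_evaluate(spec, fm)
    for m in res.metrics.values():
        assert m["balanced_accuracy"] == 1.0


def test_loso_no_leakage_from_heldout_subject():
    """Corrupting the held-out subject's labels and features must not change
    the training-fold preprocessing or tuned hyperparameters."""
    fm = _toy_study(seed=2)
    spec = ModelSpec("SVM_L", "classify_windup", grid={"C": [0.1, 1.0]},
                     tuning_folds=5, seed=0)
    res1 = loso_evaluate(spec, fm)

    corrupted = fm.copy()
    mask = corrupted["subject_id"] == "S0"
    corrupted.loc[mask, "windup"] = "circle"
    corrupted.loc[mask, ["f0", "f1", "f2", "f3"]] = 99.0
    res2 = loso_evaluate(spec, corrupted)

    f1 = next(f for f in res1.fold_info if f.subject_id == "S0")
    f2 = next(f for f in res2.fold_info if f.subject_id == "S0")
    assert f1.prune.retained == f2.prune.retained
    assert np.allclose(f1.scaler.mean, f2.scaler.mean)
    assert np.allclose(f1.scaler.scale, f2.scaler.scale)
    assert f1.best_params == f2.best_params


def test_loso_needs_two_subjects():
    fm = _toy_study(n_subj=1)
    spec = ModelSpec("SVM_L", "classify_windup", grid={"C": [1.0]})
    with pytest.raises(ContractError):
        loso_evaluate(spec, fm)


# ---------------------------------------------------------------------------
# permutation importance


def test_permutation_importance_known_dependence():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(200, 3))
    y = 3.0 * X[:, 0] + 20.0  # feature 0 only; f1, f2 pure noise
    spec = ModelSpec("SVM_L", "regress_velocity", grid={"C": [10.0]}, seed=0)
    est = make_estimator(spec, {"C": 10.0})
    est.fit(X, y)
    imp = permutation_importance(est, X, y, ["f0", "f1", "f2"],
                                 is_classification=False, reps=5, seed=0)
    top = imp.iloc[0]
    assert top["feature"] == "f0"
    assert top["importance"] == 100.0
    assert (imp.set_index("feature").loc[["f1", "f2"], "importance"] < 5.0).all()
    imp2 = permutation_importance(est, X, y, ["f0", "f1", "f2"],
                                  is_classification=False, reps=5, seed=0)
    assert imp.equals(imp2)
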