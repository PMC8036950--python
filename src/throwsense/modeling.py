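"""Model fitting and evaluation under leave-one-subject-out cross-validation.

Four model families are supported for both classification (approach type,
wind-up type) and regression (peak ball velocity): random forest (RF), linear
support-vector machine (SVM_L), polynomial-kernel support-vector machine
(SVM_P) and gradient boosting machine (GBM).  Every family runs through the
identical pipeline skeleton inside each LOSO fold:

    correlation-prune (|r| > 0.95) -> standardize -> tune (k-fold CV) ->
    fit -> predict the held-out subject

Pruning and standardization are fit on the training subjects only by default,
which prevents information from the held-out subject leaking into
preprocessing; ``global_preprocess=True`` reproduces the alternative reading
in which preprocessing happens once on the pooled matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.model_selection import KFold, ParameterGrid, StratifiedKFold
from sklearn.svm import SVC, SVR

from .errors import ContractError
from .feature_extraction import feature_columns

logger = logging.getLogger(__name__)

FAMILIES = ("RF", "SVM_L", "SVM_P", "GBM")
TASKS = ("classify_approach", "classify_windup", "regress_velocity")

#: task -> label column holding the prediction target
TARGET_OF = {
    "classify_approach": "approach",
    "classify_windup": "windup",
    "regress_velocity": "velocity_mps",
}

DEFAULT_GRIDS: dict[str, dict] = {
    "RF": {"n_estimators": [500], "max_features": ["sqrt", 0.333]},
    "SVM_L": {"C": [0.1, 1.0, 10.0]},
    # inhomogeneous kernel (coef0=1): the homogeneous polynomial kernel is
    # ill-conditioned on standardized features
    "SVM_P": {"C": [0.1, 1.0, 10.0], "degree": [2, 3], "coef0": [1.0]},
    "GBM": {"n_estimators": [100, 300], "max_depth": [2, 3], "learning_rate": [0.05, 0.1]},
}


@dataclass
class ModelSpec:
    family: str
    task: str
    grid: dict | None = None
    tuning_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ContractError(f"unknown family {self.family!r}")
        if self.task not in TASKS:
            raise ContractError(f"unknown task {self.task!r}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ContractError("hyperparameter grid must be non-empty")
        if self.tuning_folds < 2:
            raise ContractError("tuning needs k >= 2 folds")

    @property
    def is_classification(self) -> bool:
        return self.task.startswith("classify")


def make_estimator(spec: ModelSpec, params: dict):
    """Instantiate the sklearn estimator for one grid point."""
    cls = spec.is_classification
    if spec.family == "RF":
        est = (RandomForestClassifier if cls else RandomForestRegressor)(
            random_state=spec.seed, **params
        )
    elif spec.family == "SVM_L":
        est = SVC(kernel="linear", **params) if cls else SVR(kernel="linear", **params)
    elif spec.family == "SVM_P":
        est = SVC(kernel="poly", **params) if cls else SVR(kernel="poly", **params)
    else:  # GBM
        est = (GradientBoostingClassifier if cls else GradientBoostingRegressor)(
            random_state=spec.seed, **params
        )
    return est


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class PruneResult:
    retained: list[str]
    removed: dict[str, float]  # feature -> |r| that triggered its removal
    cutoff: float
    constant_flagged: list[str] = field(default_factory=list)


def correlation_prune(fm: pd.DataFrame, cutoff: float = 0.95) -> PruneResult:
    """Greedy removal of highly correlated features.

    While any feature pair has |r| above the cutoff, take the currently worst
    pair and drop the member with the larger mean absolute correlation to all
    remaining features (ties: drop the later column).  Constant columns have
    undefined correlation and are treated as r = 0 against everything.
    """
    feats = feature_columns(fm)
    if len(feats) < 2:
        raise ContractError("pruning needs at least 2 feature columns")
    X = fm[feats].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ContractError("feature matrix contains non-finite values")

    sd = X.std(axis=0)
    tol = 1e-12 * np.maximum(1.0, np.abs(X.mean(axis=0)))
    constant = [f for f, s, t in zip(feats, sd, tol) if s <= t]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.abs(np.nan_to_num(R, nan=0.0))
    np.fill_diagonal(R, 0.0)

    alive = list(range(len(feats)))
    removed: dict[str, float] = {}
    while True:
        sub = R[np.ix_(alive, alive)]
        flat = int(np.argmax(sub))
        i, j = divmod(flat, len(alive))
        worst = sub[i, j]
        if worst <= cutoff:
            break
        mean_i = sub[i].sum() / (len(alive) - 1)
        mean_j = sub[j].sum() / (len(alive) - 1)
        # drop the member more correlated with everything else; ties -> later column
        # (i < j always holds: argmax hits the upper triangle first in row-major order)
        drop_local = j if mean_j >= mean_i else i
        victim = alive[drop_local]
        removed[feats[victim]] = float(worst)
        alive.remove(victim)
        if len(alive) < 2:
            break

    return PruneResult(
        retained=[feats[k] for k in alive],
        removed=removed,
        cutoff=cutoff,
        constant_flagged=constant,
    )


@dataclass
class StandardizeParams:
    columns: list[str]
    mean: np.ndarray
    scale: np.ndarray
    zero_sd_columns: list[str] = field(default_factory=list)


def standardize_fit(train: pd.DataFrame, columns: list[str] | None = None) -> StandardizeParams:
    """Column means and standard deviations of the training data.

    Zero-sd columns get scale 1 (values become deviations from the mean)."""
    columns = columns if columns is not None else feature_columns(train)
    X = train[columns].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    zero = [c for c, s in zip(columns, scale) if s == 0.0]
    scale = np.where(scale == 0.0, 1.0, scale)
    return StandardizeParams(columns=list(columns), mean=mean, scale=scale, zero_sd_columns=zero)


def standardize_apply(params: StandardizeParams, data: pd.DataFrame) -> np.ndarray:
    missing = [c for c in params.columns if c not in data.columns]
    if missing:
        raise ContractError(f"data lacks standardized column(s): {missing}")
    X = data[params.columns].to_numpy(dtype=float)
    return (X - params.mean) / params.scale


# ---------------------------------------------------------------------------
# metrics


def class_metrics(truth, pred, classes=None) -> dict[str, dict[str, float]]:
    """One-vs-rest sensitivity, specificity, balanced accuracy and F1 per class."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ContractError("truth and pred must have equal length")
    classes = list(classes) if classes is not None else sorted(set(truth))
    out: dict[str, dict[str, float]] = {}
    for c in classes:
        tp = int(np.sum((truth == c) & (pred == c)))
        fn = int(np.sum((truth == c) & (pred != c)))
        fp = int(np.sum((truth != c) & (pred == c)))
        tn = int(np.sum((truth != c) & (pred != c)))
        if tp + fn == 0:
            out[c] = {k: float("nan") for k in
                      ("sensitivity", "specificity", "balanced_accuracy", "f1")}
            out[c]["undefined"] = True
            continue
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp else float("nan")
        out[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": (sens + spec) / 2.0,
            "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
        }
    return out


def reg_metrics(truth_mps, pred_mps) -> dict[str, float]:
    """MAE (m/s), RMSE (m/s) and MAPE (%) of velocity predictions."""
    t = np.asarray(truth_mps, dtype=float)
    p = np.asarray(pred_mps, dtype=float)
    if t.shape != p.shape:
        raise ContractError("truth and pred must have equal length")
    e = p - t
    out = {
        "mae": float(np.mean(np.abs(e))),
        "rmse": float(np.sqrt(np.mean(e * e))),
    }
    if np.any(t <= 0):
        logger.warning("non-positive truth values: MAPE undefined, reported as nan")
        out["mape"] = float("nan")
    else:
        out["mape"] = float(100.0 * np.mean(np.abs(e) / t))
    return out


def macro_f1(truth, pred, classes=None) -> float:
    m = class_metrics(truth, pred, classes)
    f1s = [v["f1"] for v in m.values() if not v.get("undefined")]
    return float(np.mean(f1s)) if f1s else float("nan")


# ---------------------------------------------------------------------------
# tuning and LOSO evaluation


def tune(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> dict:
    """Pick the grid point with best mean k-fold CV score.

    Score is accuracy for classification and negative MAE for regression;
    ties resolve to the earlier grid point.  A single-point grid is returned
    directly without cross-validation.
    """
    grid = list(ParameterGrid(spec.grid))
    if len(grid) == 1:
        return grid[0]
    if X.shape[0] < spec.tuning_folds:
        raise ContractError("fewer training rows than tuning folds")
    if spec.is_classification:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < spec.tuning_folds:
            raise ContractError("a class has fewer members than tuning folds")
        splitter = StratifiedKFold(n_splits=spec.tuning_folds, shuffle=True, random_state=spec.seed)
    else:
        splitter = KFold(n_splits=spec.tuning_folds, shuffle=True, random_state=spec.seed)

    best_params, best_score = None, -np.inf
    for params in grid:
        scores = []
        for tr, va in splitter.split(X, y if spec.is_classification else None):
            est = make_estimator(spec, params)
            est.fit(X[tr], y[tr])
            yhat = est.predict(X[va])
            if spec.is_classification:
                scores.append(float(np.mean(yhat == y[va])))
            else:
                scores.append(-float(np.mean(np.abs(yhat - y[va].astype(float)))))
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, params
    return best_params


@dataclass
class FoldInfo:
    subject_id: str
    prune: PruneResult
    scaler: StandardizeParams
    best_params: dict


@dataclass
class EvaluationResult:
    task: str
    family: str
    predictions: pd.DataFrame  # subject_id, truth, pred
    metrics: dict              # per-class dict or reg-metric dict
    per_subject: pd.DataFrame  # one row per subject with fold-level metrics
    fold_info: list[FoldInfo] = field(default_factory=list)


def loso_evaluate(
    spec: ModelSpec,
    fm: pd.DataFrame,
    cutoff: float = 0.95,
    global_preprocess: bool = False,
) -> EvaluationResult:
    """Leave-one-subject-out evaluation of one model family on one feature set."""
    target = TARGET_OF[spec.task]
    subjects = [s for s in fm["subject_id"].unique()]
    if len(subjects) < 2:
        raise ContractError("LOSO needs at least 2 subjects")

    if global_preprocess:
        global_prune = correlation_prune(fm, cutoff)
        global_scaler = standardize_fit(fm, global_prune.retained)

    pred_rows = []
    subj_rows = []
    folds: list[FoldInfo] = []
    for s in subjects:
        train = fm[fm["subject_id"] != s]
        test = fm[fm["subject_id"] == s]
        if len(test) == 0:
            logger.info("subject %s has no rows, skipped", s)
            continue
        if global_preprocess:
            prune, scaler = global_prune, global_scaler
        else:
            prune = correlation_prune(train, cutoff)
            scaler = standardize_fit(train, prune.retained)
        Xtr = standardize_apply(scaler, train)
        Xte = standardize_apply(scaler, test)
        ytr = train[target].to_numpy()
        yte = test[target].to_numpy()
        best = tune(spec, Xtr, ytr)
        est = make_estimator(spec, best)
        est.fit(Xtr, ytr)
        yhat = est.predict(Xte)

        folds.append(FoldInfo(subject_id=s, prune=prune, scaler=scaler, best_params=best))
        for t, p in zip(yte, yhat):
            pred_rows.append({"subject_id": s, "truth": t, "pred": p})
        if spec.is_classification:
            subj_rows.append(
                {
                    "subject_id": s,
                    "f1_macro": macro_f1(yte, yhat, classes=sorted(fm[target].unique())),
                    "accuracy": float(np.mean(yhat == yte)),
                }
            )
        else:
            rm = reg_metrics(yte, yhat)
            subj_rows.append({"subject_id": s, **rm})

    predictions = pd.DataFrame(pred_rows)
    if spec.is_classification:
        metrics = class_metrics(
            predictions["truth"], predictions["pred"], classes=sorted(fm[target].unique())
        )
    else:
        metrics = reg_metrics(predictions["truth"], predictions["pred"])
    return EvaluationResult(
        task=spec.task,
        family=spec.family,
        predictions=predictions,
        metrics=metrics,
        per_subject=pd.DataFrame(subj_rows),
        fold_info=folds,
    )


def permutation_importance(
    est,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    is_classification: bool,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance scaled to 0-100.

    Importance of a feature is the mean drop in model score (accuracy, or
    negative MAE for regression) over ``reps`` shuffles of its column;
    negative drops clip to 0, then the table is scaled so the most important
    feature scores exactly 100.
    """
    if reps < 1:
        raise ContractError("reps must be >= 1")
    rng = np.random.default_rng(seed)

    def score(Xs):
        yhat = est.predict(Xs)
        if is_classification:
            return float(np.mean(yhat == y))
        return -float(np.mean(np.abs(yhat - y.astype(float))))

    base = score(X)
    raw = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(reps):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            drops.append(base - score(Xp))
        raw[j] = np.mean(drops)
    raw = np.clip(raw, 0.0, None)
    scaled = 100.0 * raw / raw.max() if raw.max() > 0 else raw
    return (
        pd.DataFrame({"feature": feature_names, "importance": scaled})
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
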