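"""Feature screening and the bagged-tree recurrence classifier.

The modelling chain mirrors the clinical study's protocol: standardize the
110 partition features, drop redundant features by pairwise correlation,
run recursive feature elimination (RFE) scored by stratified 5-fold
cross-validated AUC, then fit a bagged decision-tree ensemble

    RF(x) = (1/B) * sum_i T_i(x)

with tree depth and ensemble size B chosen by grid search.  Predicted
probabilities use the tree average (the RF(x) form); hard class labels use
majority voting over the trees.  The cohort splits 80/20 into training and
validation, stratified by the relapse label, and *every* fitted quantity —
standardization constants, dropped columns, the RFE subset, the grid-search
winner — is learned on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "REFERENCE_SELECTED_FEATURES",
    "DEFAULT_GRID_SEARCH",
    "Standardizer",
    "ScreeningResult",
    "ModelReport",
    "BaggedTreeEnsemble",
    "standardize",
    "correlation_filter",
    "rfe_cv",
    "train_model",
    "split_train_validation",
    "evaluate",
    "screen_and_train",
]

# Feature subset reported for the reference clinical cohort's final model
# (22 parameters), kept as a named comparison set; station labels for the
# LN indices follow the canonical map (LN9=5, LN10=6, LN11=7, LN13=10R,
# LN14=10L).  Selection in this package is always data-driven.
REFERENCE_SELECTED_FEATURES: tuple[str, ...] = (
    "RctvLN2", "RctvLN5", "RctvLN6", "RctvLN7", "RctvLN8", "RctvLN9",
    "RIctvLN2", "RIctvLN7", "RIctvLN8", "RIctvLN14",
    "RgtvLN2", "RgtvLN8", "RgtvLN9", "RgtvLN11", "RgtvLN14",
    "RIgtvLN7", "RIgtvLN10", "RIgtvLN13",
    "gtvnd_volume", "image_resolution", "n_ln_gtvnd", "gtv_size",
)

DEFAULT_GRID_SEARCH: dict[str, list] = {
    "max_depth": [3, 5, 7, None],
    "n_estimators": [100, 200, 500],
}


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Standardizer:
    """Per-column (mean, sd) learned on training rows.

    Population-sd convention (ddof=0).  Constant columns (sd = 0) map to
    all-zeros and are flagged so downstream stages can ignore them.
    """

    mean: pd.Series
    sd: pd.Series
    constant_columns: tuple[str, ...]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        sd = self.sd.replace(0.0, 1.0)
        Z = (X - self.mean) / sd
        return Z


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Standardize columns to mean 0, sd 1 (population sd); return the
    transform so validation rows can be mapped with training constants."""
    if len(X) < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    const = tuple(sd.index[sd == 0.0])
    tr = Standardizer(mean=mean, sd=sd, constant_columns=const)
    return tr.transform(X), tr


# ---------------------------------------------------------------------------
# Correlation-redundancy filter
# ---------------------------------------------------------------------------


def correlation_filter(
    X: pd.DataFrame,
    y: Optional[Sequence[int]] = None,
    threshold: float = 0.95,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one feature of every highly correlated pair.

    Pairs with |Pearson r| >= ``threshold`` are scanned in column order;
    within a pair the feature with the weaker absolute (point-biserial)
    correlation to the label is dropped, ties keeping the earlier column.
    Without a label the later column of each pair is dropped.  Returns
    (kept column names, log of (kept, dropped, |r|) triples).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cols = list(X.columns)
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr = np.nan_to_num(corr)  # constant columns: undefined -> uncorrelated
    if y is not None:
        yv = np.asarray(y, dtype=float)
        label_r = np.zeros(len(cols))
        if yv.std() > 0:
            centered = arr - arr.mean(axis=0)
            yc = yv - yv.mean()
            denom = sd * yv.std() * len(yv)
            with np.errstate(invalid="ignore", divide="ignore"):
                label_r = np.abs(np.where(denom > 0, centered.T @ yc / denom, 0.0))
    else:
        label_r = None

    dropped: set[int] = set()
    log: list[tuple[str, str, float]] = []
    p = len(cols)
    for i in range(p):
        if i in dropped:
            continue
        for j in range(i + 1, p):
            if j in dropped:
                continue
            r = abs(corr[i, j])
            if r < threshold or (sd[i] == 0 or sd[j] == 0):
                continue
            if label_r is not None and label_r[j] > label_r[i]:
                keep, drop = j, i
            else:
                keep, drop = i, j  # tie or no label: keep the earlier column
            dropped.add(drop)
            log.append((cols[keep], cols[drop], float(r)))
            if drop == i:
                break
    kept = [c for k, c in enumerate(cols) if k not in dropped]
    return kept, log


# ---------------------------------------------------------------------------
# RFE with stratified cross-validation
# ---------------------------------------------------------------------------


@dataclass
class ScreeningResult:
    """Outcome of correlation filtering + RFE."""

    dropped_correlated: list[tuple[str, str, float]]
    rfe_path: list[tuple[int, float]]      # (subset size, mean CV AUC)
    selected: list[str]
    ranking: list[str] = field(default_factory=list)  # elimination order, last = most important

    def to_dict(self) -> dict:
        return {
            "dropped_correlated": [list(t) for t in self.dropped_correlated],
            "rfe_path": [[int(k), float(v)] for k, v in self.rfe_path],
            "selected": list(self.selected),
            "ranking": list(self.ranking),
        }


def _make_forest(seed: int, n_estimators: int = 100, max_depth: Optional[int] = None
                 ) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def _cv_auc_and_importance(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int,
    n_estimators: int, max_depth: Optional[int],
) -> tuple[float, np.ndarray]:
    """Mean held-out AUC and mean impurity importance over stratified folds."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs, imps = [], []
    for tr, te in skf.split(X, y):
        clf = _make_forest(seed, n_estimators, max_depth)
        clf.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.predict_proba(X[te])[:, 1]))
        imps.append(clf.feature_importances_)
    return float(np.mean(aucs)), np.mean(imps, axis=0)


def rfe_cv(
    X: pd.DataFrame,
    y: Sequence[int],
    folds: int = 5,
    step: int = 1,
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: Optional[int] = None,
    min_features: int = 1,
) -> ScreeningResult:
    """Recursive feature elimination scored by stratified-CV mean AUC.

    At each subset size the ensemble is fit per fold, the mean held-out AUC
    is recorded, features are ranked by mean impurity importance across the
    folds, and the ``step`` lowest-ranked features are removed.  The
    selected subset maximizes mean CV AUC, ties resolved toward the smaller
    subset.  The whole path is reproducible from ``seed``.
    """
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present for RFE")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    cols = list(X.columns)
    arr = X.to_numpy(dtype=float)
    active = list(range(len(cols)))
    path: list[tuple[int, float]] = []
    best: dict[int, list[int]] = {}
    eliminated: list[str] = []
    while True:
        auc, imp = _cv_auc_and_importance(
            arr[:, active], yv, folds, seed, n_estimators, max_depth
        )
        path.append((len(active), auc))
        best[len(active)] = list(active)
        if len(active) <= min_features:
            break
        k = min(step, len(active) - min_features)
        order = np.argsort(imp, kind="stable")  # ascending importance
        doomed = sorted(order[:k], reverse=True)
        for d in doomed:
            eliminated.append(cols[active[d]])
            del active[d]
    # max CV AUC; ties -> smaller subset
    best_size = min(
        (size for size, auc in path if auc == max(a for _s, a in path)),
    )
    selected = [cols[j] for j in best[best_size]]
    ranking = eliminated + [cols[j] for j in best[min(best)]][::-1]
    return ScreeningResult(
        dropped_correlated=[],
        rfe_path=path,
        selected=selected,
        ranking=ranking,
    )


# ---------------------------------------------------------------------------
# Bagged-tree ensemble with averaging scores and voting labels
# ---------------------------------------------------------------------------


class BaggedTreeEnsemble:
    """Bootstrap-aggregated decision trees with random feature subsetting.

    Thin wrapper over scikit-learn's forest: ``predict_proba`` averages the
    per-tree class probabilities (the RF(x) = (1/B) sum T_i(x) form) while
    ``predict`` takes the majority vote of the trees' hard labels — the two
    aggregation rules the protocol describes, kept side by side.
    """

    def __init__(self, n_estimators: int = 200, max_depth: Optional[int] = None,
                 seed: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.seed = seed
        self._forest: Optional[RandomForestClassifier] = None
        self.feature_names_: Optional[list[str]] = None

    def fit(self, X: pd.DataFrame | np.ndarray, y: Sequence[int]) -> "BaggedTreeEnsemble":
        yv = np.asarray(y, dtype=int)
        if len(np.unique(yv)) < 2:
            raise ValueError("both classes must be present to fit")
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        self._forest = _make_forest(self.seed, self.n_estimators, self.max_depth)
        self._forest.fit(np.asarray(X, dtype=float), yv)
        return self

    def _check(self, X) -> np.ndarray:
        if self._forest is None:
            raise RuntimeError("model is not fitted")
        if isinstance(X, pd.DataFrame):
            if self.feature_names_ is not None:
                X = X[self.feature_names_]
            X = X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict_proba(self, X) -> np.ndarray:
        """Average of per-tree class probabilities, shape (n, 2)."""
        return self._forest.predict_proba(self._check(X))

    def predict_score(self, X) -> np.ndarray:
        """Averaged probability of the positive class."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        """Majority vote of the trees' hard labels (ties -> positive)."""
        arr = self._check(X)
        votes = np.stack([t.predict(arr) for t in self._forest.estimators_])
        return (votes.mean(axis=0) >= 0.5).astype(int)

    @property
    def feature_importances_(self) -> np.ndarray:
        if self._forest is None:
            raise RuntimeError("model is not fitted")
        return self._forest.feature_importances_


def train_model(
    X: pd.DataFrame,
    y: Sequence[int],
    grid: Optional[dict[str, list]] = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[BaggedTreeEnsemble, dict]:
    """Grid-search tree depth and ensemble size by stratified CV AUC, then
    refit the winner on all provided rows.  Ties keep the earlier grid
    point (scan order: depth-major, as listed in the grid)."""
    grid = grid or DEFAULT_GRID_SEARCH
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    best_auc, best_params = -np.inf, None
    for depth in grid["max_depth"]:
        for n_est in grid["n_estimators"]:
            auc, _ = _cv_auc_and_importance(arr, yv, folds, seed, n_est, depth)
            if auc > best_auc:
                best_auc, best_params = auc, {"max_depth": depth, "n_estimators": n_est}
    model = BaggedTreeEnsemble(seed=seed, **best_params).fit(X, yv)
    info = {"best_params": best_params, "cv_auc": float(best_auc)}
    return model, info


def split_train_validation(
    ids: Sequence,
    y: Sequence[int],
    fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list, list]:
    """Stratified, disjoint, exhaustive train/validation split of ids."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    yv = np.asarray(y, dtype=int)
    counts = np.bincount(yv, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    train_ids, val_ids = train_test_split(
        list(ids), train_size=fraction, random_state=seed, stratify=yv, shuffle=True
    )
    return list(train_ids), list(val_ids)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate(model: BaggedTreeEnsemble, X: pd.DataFrame, y: Sequence[int]
             ) -> tuple[dict[str, float], list[tuple[float, float, float]]]:
    """Threshold metrics at score 0.5 plus rank-based AUC and ROC points."""
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("AUC undefined: only one class present")
    score = model.predict_score(X)
    pred = (score >= 0.5).astype(int)
    tp = int(((pred == 1) & (yv == 1)).sum())
    fp = int(((pred == 1) & (yv == 0)).sum())
    fn = int(((pred == 0) & (yv == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    metrics = {
        "accuracy": float((pred == yv).mean()),
        "auc": float(roc_auc_score(yv, score)),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
    }
    fpr, tpr, thr = roc_curve(yv, score)
    roc_points = [(float(f), float(t), float(th)) for f, t, th in zip(fpr, tpr, thr)]
    return metrics, roc_points


@dataclass
class ModelReport:
    """Full record of one screened-and-trained model run."""

    split_seed: int
    n_train: int
    n_validation: int
    screening: ScreeningResult
    best_hyperparameters: dict
    metrics_train: dict[str, float]
    metrics_validation: dict[str, float]
    roc_points: list[tuple[float, float, float]]

    def to_dict(self) -> dict:
        return {
            "split_seed": self.split_seed,
            "n_train": self.n_train,
            "n_validation": self.n_validation,
            "screening": self.screening.to_dict(),
            "best_hyperparameters": self.best_hyperparameters,
            "metrics_train": self.metrics_train,
            "metrics_validation": self.metrics_validation,
            "roc_points": [list(p) for p in self.roc_points],
        }


def screen_and_train(
    features: pd.DataFrame,
    label_column: str = "relapse",
    fraction: float = 0.8,
    correlation_threshold: float = 0.95,
    folds: int = 5,
    rfe_step: int = 1,
    grid: Optional[dict[str, list]] = None,
    seed: int = 0,
    rfe_n_estimators: int = 100,
) -> tuple[ModelReport, BaggedTreeEnsemble, Standardizer]:
    """End-to-end modelling on a feature table (110 columns + label).

    Splits 80/20 stratified, then — on training rows only — standardizes,
    correlation-filters, runs RFE, grid-searches the ensemble, and finally
    evaluates on both subsets with the training-derived transforms.
    """
    X_all = features.drop(columns=[label_column])
    y_all = features[label_column].astype(int)
    train_ids, val_ids = split_train_validation(
        features.index, y_all, fraction=fraction, seed=seed
    )
    X_tr, y_tr = X_all.loc[train_ids], y_all.loc[train_ids]
    X_va, y_va = X_all.loc[val_ids], y_all.loc[val_ids]

    Z_tr, scaler = standardize(X_tr)
    kept, corr_log = correlation_filter(Z_tr, y_tr, threshold=correlation_threshold)
    kept = [c for c in kept if c not in scaler.constant_columns]
    screening = rfe_cv(
        Z_tr[kept], y_tr, folds=folds, step=rfe_step, seed=seed,
        n_estimators=rfe_n_estimators,
    )
    screening.dropped_correlated = corr_log
    sel = screening.selected

    model, fit_info = train_model(Z_tr[sel], y_tr, grid=grid, folds=folds, seed=seed)
    Z_va = scaler.transform(X_va)
    metrics_tr, _ = evaluate(model, Z_tr[sel], y_tr)
    metrics_va, roc_points = evaluate(model, Z_va[sel], y_va)
    report = ModelReport(
        split_seed=seed,
        n_train=len(train_ids),
        n_validation=len(val_ids),
        screening=screening,
        best_hyperparameters=fit_info["best_params"],
        metrics_train=metrics_tr,
        metrics_validation=metrics_va,
        roc_points=roc_points,
    )
    return report, model, scaler
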