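"""Hyperparameter grid search and Youden's J threshold selection.

The forest is tuned as a regression model on the 0/1 outcome: a Cartesian
grid over ``mtry = max(1, floor(x * p))`` and
``min_node_size = max(1, round(N ** y))`` (x, y in (0, 1]), scored by the
root mean squared error of held-out scores under stratified k-fold
cross-validation, pooled over folds. The operating probability threshold is
then chosen by maximizing Youden's J = sensitivity + specificity - 1 over
candidate cuts, per fold, reporting the per-fold values with their mean and
sample standard deviation. For a rare outcome the resulting cut sits far
below 0.5, near the outcome prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .forest import BootstrapForest, classify
from .knockoff_importance import sensitivity, specificity

__all__ = [
    "TuningResult",
    "ThresholdResult",
    "stratified_folds",
    "tune_grid",
    "youden_threshold",
    "youden_threshold_cv",
]


@dataclass
class TuningResult:
    grid: list[dict]
    best_x: float
    best_y: float
    best_mtry: int
    best_min_node_size: int
    best_cv_rmse: float
    folds: int
    seed: int


@dataclass
class ThresholdResult:
    per_fold_thresholds: np.ndarray
    mean_threshold: float
    sd_threshold: float


def stratified_folds(
    y: np.ndarray, k: int, seed: int = 0
) -> list[np.ndarray]:
    """k disjoint index sets with per-fold class counts differing by <= 1."""
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has only {counts.min()} members; cannot form {k} "
            "stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32 - 1))
    return [np.sort(test) for _, test in skf.split(np.zeros(y.size), y)]


def resolve_hyperparams(
    x: float, y_exp: float, p: int, n: int
) -> tuple[int, int]:
    """Map grid coordinates to (mtry, min_node_size).

    mtry = max(1, floor(x * p)); min_node_size = max(1, round(n ** y)).
    """
    if not 0.0 < x <= 1.0 or not 0.0 < y_exp <= 1.0:
        raise ValueError("grid values must lie in (0, 1]")
    mtry = max(1, int(np.floor(x * p)))
    node = max(1, int(np.round(n**y_exp)))
    return mtry, node


def tune_grid(
    X: np.ndarray,
    y: np.ndarray,
    x_grid=None,
    y_grid=None,
    k: int = 10,
    n_trees: int = 500,
    seed: int = 0,
    node_size_n: str = "full",
) -> TuningResult:
    """Cross-validated RMSE over the full (x, y) Cartesian grid.

    ``node_size_n="full"`` evaluates ``N ** y`` at the full sample size (the
    headline formula); ``"fold"`` uses each fold's training size. Ties are
    broken toward smaller mtry, then smaller min_node_size. Default grids
    are 0.1 to 1 in steps of 0.1 (100 combinations).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    x_grid = np.round(np.arange(0.1, 1.01, 0.1), 10) if x_grid is None else np.asarray(x_grid, float)
    y_grid = np.round(np.arange(0.1, 1.01, 0.1), 10) if y_grid is None else np.asarray(y_grid, float)
    if x_grid.size == 0 or y_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if ((x_grid <= 0) | (x_grid > 1)).any() or ((y_grid <= 0) | (y_grid > 1)).any():
        raise ValueError("grid values must lie in (0, 1]")
    if node_size_n not in ("full", "fold"):
        raise ValueError("node_size_n must be 'full' or 'fold'")

    constant_outcome = np.unique(y).size < 2
    folds = None if constant_outcome else stratified_folds(y, k, seed=seed)
    fold_seeds = np.random.SeedSequence(int(seed)).spawn(k)

    grid_rows = []
    for xv in x_grid:
        for yv in y_grid:
            if constant_outcome:
                mtry, node = resolve_hyperparams(xv, yv, p, n)
                grid_rows.append(
                    {"x": float(xv), "y": float(yv), "mtry": mtry,
                     "min_node_size": node, "cv_rmse": 0.0}
                )
                continue
            sq_errors = []
            mtry = node = None
            for f, test_idx in enumerate(folds):
                train_mask = np.ones(n, dtype=bool)
                train_mask[test_idx] = False
                train_idx = np.where(train_mask)[0]
                n_ref = n if node_size_n == "full" else train_idx.size
                mtry, node = resolve_hyperparams(xv, yv, p, n_ref)
                forest = BootstrapForest(
                    n_trees=n_trees, mtry=min(mtry, p), min_node_size=node,
                    mode="regression",
                    random_state=int(fold_seeds[f].generate_state(1)[0] % (2**31 - 1)),
                ).fit(X[train_idx], y[train_idx])
                scores = forest.predict_scores(X[test_idx])
                sq_errors.append((scores - y[test_idx]) ** 2)
            rmse = float(np.sqrt(np.concatenate(sq_errors).mean()))
            grid_rows.append(
                {"x": float(xv), "y": float(yv), "mtry": mtry,
                 "min_node_size": node, "cv_rmse": rmse}
            )

    best = min(
        grid_rows, key=lambda r: (r["cv_rmse"], r["mtry"], r["min_node_size"])
    )
    return TuningResult(
        grid=grid_rows,
        best_x=best["x"],
        best_y=best["y"],
        best_mtry=best["mtry"],
        best_min_node_size=best["min_node_size"],
        best_cv_rmse=best["cv_rmse"],
        folds=k,
        seed=int(seed),
    )


def youden_candidates(scores: np.ndarray) -> np.ndarray:
    """Candidate cuts: 0, 1, and midpoints of consecutive unique scores."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    return np.unique(np.concatenate([[0.0, 1.0], mids]))


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Smallest candidate threshold maximizing J = sens + spec - 1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("Youden's J needs both classes in the labels")
    best_t, best_j = None, -np.inf
    for t in youden_candidates(scores):  # ascending, so first max wins
        pred = classify(scores, t)
        j = sensitivity(labels, pred) + specificity(labels, pred) - 1.0
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def youden_threshold_cv(
    X: np.ndarray,
    y: np.ndarray,
    forest_params: dict | None = None,
    k: int = 10,
    seed: int = 0,
) -> ThresholdResult:
    """Per-fold Youden thresholds from held-out forest scores.

    Each fold's threshold comes from a regression forest trained on the
    other k-1 folds; a fold whose held-out labels collapse to one class is
    an error naming the fold (raise k or n).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, k, seed=seed)
    fold_seeds = np.random.SeedSequence(int(seed)).spawn(k)
    forest_params = dict(forest_params or {})
    forest_params.setdefault("mode", "regression")
    thresholds = np.empty(k)
    for f, test_idx in enumerate(folds):
        y_te = y[test_idx]
        if np.unique(y_te).size < 2:
            raise ValueError(
                f"fold {f} holds a single outcome class; Youden threshold "
                "undefined — increase n or decrease k"
            )
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        forest = BootstrapForest(
            random_state=int(fold_seeds[f].generate_state(1)[0] % (2**31 - 1)),
            **forest_params,
        ).fit(X[train_mask], y[train_mask])
        thresholds[f] = youden_threshold(forest.predict_scores(X[test_idx]), y_te)
    return ThresholdResult(
        per_fold_thresholds=thresholds,
        mean_threshold=float(thresholds.mean()),
        sd_threshold=float(thresholds.std(ddof=1)),
    )
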