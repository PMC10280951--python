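"""Per-participant out-of-bag permutation importance.

This is the classic forest importance whose bias the package exists to
demonstrate. For a feature j:

1. For every training participant i, predict i's outcome with i's
   *sub-forest* (the trees whose bootstrap resample excluded i) and record
   the accuracy indicator P_i.
2. Replace x_ij with a randomly selected value of feature j (drawn from the
   observed column, excluding i's own value), re-predict with the same
   sub-forest, and record the accuracy indicator P_i*.
3. VIMP_i = P_i - P_i*; the feature's importance is the average of VIMP_i
   over all participants with a non-empty sub-forest (and over
   ``n_repeats`` independent substitution draws).

The accuracy indicator thresholds the sub-forest score at 0.5 — majority
vote in classification mode, the implicit probability cut of a 0/1
regression forest otherwise. Participants in-bag for every tree contribute
nothing and are surfaced through ``n_contributing``.

A feature correlated with a true predictor gets split on by many trees, so
substituting it degrades those trees' predictions even when the feature
carries no signal beyond its correlate — the inflation this metric is known
for, and which the knockoff importance in
:mod:`knockvimp.knockoff_importance` avoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import BootstrapForest

__all__ = ["OobVimpResult", "oob_vimp_feature", "oob_vimp_all"]


@dataclass
class OobVimpResult:
    feature_name: str
    vimp: float
    n_contributing: int
    metric: str
    seed: int


def substitution_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    """Donor row for each participant: uniform over the other n-1 rows.

    Part of the reproducibility contract — a given generator state always
    yields the same donors, so results are replayable from the seed.
    """
    idx = rng.integers(0, n - 1, size=n)
    idx = idx + (idx >= np.arange(n))
    return idx


def _accuracy_indicator(
    per_tree: np.ndarray, oob_mask: np.ndarray, denom: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Sub-forest accuracy indicator per participant (NaN-safe on denom=0)."""
    with np.errstate(invalid="ignore"):
        score = np.where(denom > 0, (per_tree * oob_mask).sum(axis=0) / denom, np.nan)
    label = (score >= 0.5).astype(int)
    return (label == y).astype(float)


def oob_vimp_feature(
    forest: BootstrapForest,
    X: np.ndarray,
    y: np.ndarray,
    j: int,
    seed: int = 0,
    n_repeats: int = 5,
    method: str = "draw",
    feature_name: str | None = None,
) -> OobVimpResult:
    """Out-of-bag permutation importance of feature ``j``.

    ``method="draw"`` substitutes an independently drawn value per
    participant (the literal random-value replacement); ``method="permute"``
    applies one synchronized permutation of the column per repeat, matching
    the behaviour of permutation-importance options in standard forest
    software. Substitution streams are seeded from ``(seed, j)`` so features
    are independent but replayable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if not 0 <= j < p:
        raise ValueError(f"feature index {j} out of range for p={p}")
    if forest.n_features_in_ != p or forest.n_samples_ != n:
        raise ValueError("forest was not trained on these rows/columns")
    if method not in ("draw", "permute"):
        raise ValueError(f"unknown substitution method {method!r}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    oob_mask = (~forest.bootstrap_membership_).T.astype(float)  # (T, n)
    denom = oob_mask.sum(axis=0)
    contributing = denom > 0
    n_contributing = int(contributing.sum())

    base_acc = _accuracy_indicator(forest.tree_scores(X), oob_mask, denom, y)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(j)]))
    deltas = np.empty(n_repeats)
    for r in range(n_repeats):
        if method == "draw":
            donors = substitution_indices(rng, n)
            col = X[donors, j]
        else:
            col = X[rng.permutation(n), j]
        X_star = X.copy()
        X_star[:, j] = col
        star_acc = _accuracy_indicator(
            forest.tree_scores(X_star), oob_mask, denom, y
        )
        deltas[r] = np.mean(
            base_acc[contributing] - star_acc[contributing]
        ) if n_contributing else np.nan
    if n_contributing == 0:
        raise ValueError("no participant has a non-empty sub-forest")
    return OobVimpResult(
        feature_name=feature_name if feature_name is not None else f"X{j + 1}",
        vimp=float(deltas.mean()),
        n_contributing=n_contributing,
        metric=f"oob-accuracy@0.5[{forest.mode}]",
        seed=int(seed),
    )


def oob_vimp_all(
    forest: BootstrapForest,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_repeats: int = 5,
    method: str = "draw",
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """OOB importance for every feature, sorted descending.

    One row per feature with columns ``feature, vimp, n_contributing,
    rank``. Substitution streams are independent across features but all
    derive from the single base seed.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"X{j + 1}" for j in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length must match columns")
    rows = []
    for j in range(p):
        res = oob_vimp_feature(
            forest, X, y, j,
            seed=seed, n_repeats=n_repeats, method=method,
            feature_name=feature_names[j],
        )
        rows.append(
            {"feature": res.feature_name, "vimp": res.vimp,
             "n_contributing": res.n_contributing}
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        "vimp", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, p + 1)
    return table
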