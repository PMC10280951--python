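"""Dual-forest knockoff importance for features and named groups.

The knockoff VIMP of a group of features asks: *how much unique predictive
information does the group contribute beyond every other feature in the
model?* It compares two forests that differ only in the group of interest:

1. Knockoffs are generated once for the full sample (training and testing
   together), before splitting.
2. RF1 is trained on the true features of the training rows.
3. RF2 is trained on the same rows with every group member replaced by its
   knockoff column (all other features untouched).
4. On the held-out test rows, RF1 scores the true features and RF2 scores
   the group-swapped features; both are thresholded at the same tuned
   probability cut.
5. VIMP_sens = sensitivity(RF1) - sensitivity(RF2), VIMP_spec likewise,
   and VIMP_acc = accuracy(RF1) - accuracy(RF2).

Because the knockoff preserves the group's association with the other
features but severs its link to the outcome, a null group — even one highly
correlated with true predictors — has importance centered on zero, which is
exactly where out-of-bag permutation importance fails.

The aggregate metric difference equals the mean of per-participant
indicator deltas over the relevant class (all test rows for accuracy,
positives for sensitivity, negatives for specificity); the per-participant
deltas are retained on each result for that reading.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .forest import BootstrapForest, classify
from .grouping import GroupingScheme

__all__ = [
    "KnockoffVimpResult",
    "split_train_test",
    "sensitivity",
    "specificity",
    "knockoff_vimp_group",
    "run_study",
    "fig_filter",
]


def split_train_test(
    y: np.ndarray, test_fraction: float, stratify: bool = True, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index sets (stratified by default)."""
    y = np.asarray(y, dtype=int)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both outcome classes must be present to split")
    if stratify and counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has {counts.min()} member(s); need >= 2 to stratify"
        )
    idx = np.arange(y.size)
    train, test = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=y if stratify else None,
        random_state=int(seed) % (2**32 - 1),
    )
    return np.sort(train), np.sort(test)


def sensitivity(labels_true: np.ndarray, labels_pred: np.ndarray) -> float:
    """TP / (TP + FN). Undefined (raises) when no positives exist."""
    t = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    pos = t == 1
    if not pos.any():
        raise ValueError("sensitivity undefined: no positive labels in truth")
    return float(np.mean(p[pos] == 1))


def specificity(labels_true: np.ndarray, labels_pred: np.ndarray) -> float:
    """TN / (TN + FP). Undefined (raises) when no negatives exist."""
    t = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    neg = t == 0
    if not neg.any():
        raise ValueError("specificity undefined: no negative labels in truth")
    return float(np.mean(p[neg] == 0))


def _group_seed(base_seed: int, level: str, group_name: str) -> int:
    """Stable RF2 seed from the base seed and the group's qualified name."""
    digest = hashlib.sha256(f"{level}/{group_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class KnockoffVimpResult:
    level: str
    group_name: str
    features: list[str]
    vimp_sens: float
    vimp_spec: float
    vimp_acc: float
    test_sens_true: float
    test_spec_true: float
    threshold: float
    n_train: int
    n_test: int
    seed: int
    rf2_seed: int
    participant_deltas: np.ndarray = field(repr=False, default=None)


def _swap_columns(X: np.ndarray, X_ko: np.ndarray, cols: np.ndarray) -> np.ndarray:
    out = X.copy()
    out[:, cols] = X_ko[:, cols]
    return out


def knockoff_vimp_group(
    X: np.ndarray,
    y: np.ndarray,
    X_ko: np.ndarray,
    group_features: list[str],
    feature_names: list[str],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    forest_params: dict | None = None,
    threshold: float = 0.5,
    seed: int = 0,
    level: str = "",
    group_name: str = "",
    rf1: BootstrapForest | None = None,
) -> KnockoffVimpResult:
    """Knockoff VIMP of one feature group at a fixed threshold.

    ``rf1`` may be a forest already trained on ``X[train_idx]`` with the
    same hyperparameters, so a study sharing RF1 across groups trains it
    once. RF2 always uses an independent seed derived from ``seed`` and the
    group's qualified name.
    """
    X = np.asarray(X, dtype=float)
    X_ko = np.asarray(X_ko, dtype=float)
    y = np.asarray(y, dtype=int)
    if X_ko.shape != X.shape:
        raise ValueError(
            f"knockoff matrix shape {X_ko.shape} does not match features {X.shape}"
        )
    if not group_features:
        raise ValueError("group must contain at least one feature")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    name_to_col = {name: j for j, name in enumerate(feature_names)}
    missing = [f for f in group_features if f not in name_to_col]
    if missing:
        raise ValueError(f"group names features absent from the dataset: {missing}")
    cols = np.asarray([name_to_col[f] for f in group_features], dtype=int)

    forest_params = dict(forest_params or {})
    ss = np.random.SeedSequence([int(seed), 0])
    rf1_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
    rf2_seed = int(
        np.random.SeedSequence([int(seed), _group_seed(seed, level, group_name)])
        .generate_state(1)[0] % (2**31 - 1)
    )

    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]
    if rf1 is None:
        rf1 = BootstrapForest(random_state=rf1_seed, **forest_params).fit(X_tr, y_tr)
    X_tr_swap = _swap_columns(X_tr, X_ko[train_idx], cols)
    rf2 = BootstrapForest(random_state=rf2_seed, **forest_params).fit(X_tr_swap, y_tr)

    pred1 = classify(rf1.predict_scores(X_te), threshold)
    X_te_swap = _swap_columns(X_te, X_ko[test_idx], cols)
    pred2 = classify(rf2.predict_scores(X_te_swap), threshold)

    sens1, spec1 = sensitivity(y_te, pred1), specificity(y_te, pred1)
    sens2, spec2 = sensitivity(y_te, pred2), specificity(y_te, pred2)
    acc1 = float(np.mean(pred1 == y_te))
    acc2 = float(np.mean(pred2 == y_te))
    deltas = (pred1 == y_te).astype(float) - (pred2 == y_te).astype(float)

    return KnockoffVimpResult(
        level=level,
        group_name=group_name or "+".join(group_features),
        features=list(group_features),
        vimp_sens=sens1 - sens2,
        vimp_spec=spec1 - spec2,
        vimp_acc=acc1 - acc2,
        test_sens_true=sens1,
        test_spec_true=spec1,
        threshold=float(threshold),
        n_train=int(len(train_idx)),
        n_test=int(len(test_idx)),
        seed=int(seed),
        rf2_seed=rf2_seed,
        participant_deltas=deltas,
    )


def _auto_threshold(rf1: BootstrapForest, X_tr: np.ndarray, y_tr: np.ndarray) -> float:
    """Youden cut from RF1's out-of-bag scores on the training rows."""
    from .tuning import youden_threshold

    scores = rf1.oob_scores(X_tr)
    ok = ~np.isnan(scores)
    return youden_threshold(scores[ok], y_tr[ok])


def run_study(
    X: np.ndarray,
    y: np.ndarray,
    grouping: GroupingScheme,
    feature_names: list[str],
    knockoffs: np.ndarray | None = None,
    sampler=None,
    forest_params: dict | None = None,
    threshold: float | str = "auto",
    test_fraction: float = 0.2,
    seed: int = 0,
    replicates: int = 1,
) -> pd.DataFrame:
    """Knockoff VIMPs for every group at every level of a hierarchy.

    RF1 is trained once per replicate and shared across groups; RF2 differs
    between groups only in which columns are swapped for knockoffs. With
    ``replicates > 1`` the split, forests, and (when a fitted ``sampler``
    is supplied) the knockoff draw are re-run per replicate and the table
    reports the mean and standard deviation of each VIMP. Per-group
    failures are recorded in an ``error`` column; remaining groups still
    run.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    grouping.validate(feature_names)
    if knockoffs is None and sampler is None:
        raise ValueError("provide a knockoff matrix or a fitted sampler")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    rep_frames = []
    for rep in range(replicates):
        rep_ss = np.random.SeedSequence([int(seed), int(rep)])
        split_seed, ko_seed, group_base = [
            int(s.generate_state(1)[0] % (2**31 - 1)) for s in rep_ss.spawn(3)
        ]
        if sampler is not None:
            X_ko = sampler.sample(X, seed=ko_seed)
        else:
            X_ko = np.asarray(knockoffs, dtype=float)
        train_idx, test_idx = split_train_test(
            y, test_fraction, stratify=True, seed=split_seed
        )
        forest_params_ = dict(forest_params or {})
        rf1_seed = int(
            np.random.SeedSequence([group_base, 0]).generate_state(1)[0]
            % (2**31 - 1)
        )
        rf1 = BootstrapForest(random_state=rf1_seed, **forest_params_).fit(
            X[train_idx], y[train_idx]
        )
        thr = (
            _auto_threshold(rf1, X[train_idx], y[train_idx])
            if threshold == "auto"
            else float(threshold)
        )
        rows = []
        for level, group_name, members in grouping.iter_groups():
            try:
                res = knockoff_vimp_group(
                    X, y, X_ko, members, feature_names,
                    train_idx, test_idx,
                    forest_params=forest_params_,
                    threshold=thr,
                    seed=group_base,
                    level=level,
                    group_name=group_name,
                    rf1=rf1,
                )
                rows.append({
                    "level": level, "group": group_name,
                    "n_features": len(members),
                    "vimp_sens": res.vimp_sens, "vimp_spec": res.vimp_spec,
                    "vimp_acc": res.vimp_acc,
                    "sens_true": res.test_sens_true,
                    "spec_true": res.test_spec_true,
                    "threshold": thr, "replicate": rep, "error": "",
                })
            except ValueError as exc:
                rows.append({
                    "level": level, "group": group_name,
                    "n_features": len(members),
                    "vimp_sens": np.nan, "vimp_spec": np.nan,
                    "vimp_acc": np.nan, "sens_true": np.nan,
                    "spec_true": np.nan, "threshold": thr,
                    "replicate": rep, "error": str(exc),
                })
        rep_frames.append(pd.DataFrame(rows))

    table = pd.concat(rep_frames, ignore_index=True)
    if replicates == 1:
        return table.drop(columns=["replicate"])
    metrics = ["vimp_sens", "vimp_spec", "vimp_acc", "sens_true", "spec_true"]
    agg = table.groupby(["level", "group"], sort=False).agg(
        n_features=("n_features", "first"),
        **{m: (m, "mean") for m in metrics},
        **{f"{m}_sd": (m, lambda v: float(np.std(v, ddof=1))) for m in metrics},
        threshold=("threshold", "mean"),
        error=("error", lambda v: "; ".join(x for x in v if x)),
    ).reset_index()
    return agg


def fig_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Report view keeping only groups with both VIMP_sens and VIMP_spec > 0."""
    keep = (table["vimp_sens"] > 0) & (table["vimp_spec"] > 0)
    return table[keep].reset_index(drop=True)
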