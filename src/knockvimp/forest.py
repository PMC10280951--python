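"""Bagged tree ensembles with explicit bootstrap bookkeeping.

:class:`BootstrapForest` is classic Breiman bagging: each of T trees is fit
on a size-n resample drawn with replacement, with ``mtry`` candidate
features per split and a minimum terminal node size. Unlike the stock
ensemble classes, the bootstrap resample for every tree is drawn and
*recorded* here, because per-participant out-of-bag analysis needs the
exact membership table: the trees whose resample excluded participant i
form i's "sub-forest", and downstream importance methods predict for i
using only those trees.

Regression mode (a probability machine on a 0/1 outcome, mean of tree
outputs) is the default; classification mode (majority vote) exists for the
out-of-bag permutation importance reproduction.
"""

from __future__ import annotations

import pickle
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = ["BootstrapForest", "classify"]


def classify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Binary labels under the ``score >= threshold -> 1`` rule."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


class BootstrapForest(BaseEstimator):
    """Bagged decision trees with a recorded bootstrap membership table.

    Parameters
    ----------
    n_trees : int, default 500
        Ensemble size T.
    mtry : int or None, default None
        Candidate features per split; ``None`` uses ``max(1, floor(sqrt(p)))``.
    min_node_size : int, default 5 (regression) — see ``fit``
        Minimum terminal node size. ``None`` resolves to 5 in regression
        mode and 1 in classification mode, the conventional defaults.
    mode : {"regression", "classification"}
        Regression averages raw tree outputs (probability machine);
        classification averages per-tree 0/1 votes.
    random_state : int, optional
        Base seed; per-tree bootstrap and split streams are spawned from it.

    Attributes
    ----------
    trees_ : list of fitted sklearn trees.
    bootstrap_counts_ : (n, T) int array, multiplicity of row i in tree t's
        resample (columns sum to n).
    bootstrap_membership_ : (n, T) bool array, ``counts > 0``.
    n_features_in_ : number of training columns, enforced at prediction.
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry: int | None = None,
        min_node_size: int | None = None,
        mode: str = "regression",
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.mode = mode
        self.random_state = random_state

    # -- training ---------------------------------------------------------

    def fit(self, X, y) -> "BootstrapForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if y.shape != (n,):
            raise ValueError("y length must match X rows")
        if not np.isin(y, [0, 1]).all():
            raise ValueError("outcome must be coded 0/1")
        if self.mode not in ("regression", "classification"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "classification" and np.unique(y).size < 2:
            raise ValueError("classification mode requires both outcome classes")
        mtry = self.mtry if self.mtry is not None else max(1, int(np.sqrt(p)))
        if not 1 <= mtry <= p:
            raise ValueError(f"mtry must lie in [1, {p}], got {mtry}")
        node = self.min_node_size
        if node is None:
            node = 5 if self.mode == "regression" else 1
        if node < 1:
            raise ValueError("min_node_size must be >= 1")
        node = min(node, n)

        ss = np.random.SeedSequence(self.random_state)
        tree_seeds = ss.spawn(self.n_trees)
        self.trees_ = []
        counts = np.zeros((n, self.n_trees), dtype=np.int32)
        y_fit = y.astype(float) if self.mode == "regression" else y.astype(int)
        for t, child in enumerate(tree_seeds):
            boot_ss, split_ss = child.spawn(2)
            rng = np.random.default_rng(boot_ss)
            idx = rng.integers(0, n, size=n)
            np.add.at(counts[:, t], idx, 1)
            split_seed = int(split_ss.generate_state(1)[0] % (2**31 - 1))
            if self.mode == "regression":
                tree = DecisionTreeRegressor(
                    max_features=mtry,
                    min_samples_leaf=node,
                    random_state=split_seed,
                )
            else:
                tree = DecisionTreeClassifier(
                    max_features=mtry,
                    min_samples_leaf=node,
                    random_state=split_seed,
                )
            tree.fit(X[idx], y_fit[idx])
            self.trees_.append(tree)
        self.bootstrap_counts_ = counts
        self.bootstrap_membership_ = counts > 0
        self.n_features_in_ = p
        self.n_samples_ = n
        self.mtry_ = mtry
        self.min_node_size_ = node
        self.classes_ = np.unique(y)
        return self

    # -- prediction -------------------------------------------------------

    def tree_scores(self, X) -> np.ndarray:
        """(T, m) matrix of per-tree outputs for the query rows.

        Regression: raw tree predictions. Classification: the predicted
        class (0/1) of each tree — the vote it casts.
        """
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"forest was trained with {self.n_features_in_}"
            )
        out = np.empty((len(self.trees_), X.shape[0]))
        for t, tree in enumerate(self.trees_):
            out[t] = tree.predict(X)
        return out

    def predict_scores(
        self, X, tree_subset: Sequence[int] | None = None
    ) -> np.ndarray:
        """Mean tree output over ``tree_subset`` (all trees by default)."""
        per_tree = self.tree_scores(X)
        if tree_subset is None:
            return per_tree.mean(axis=0)
        subset = np.asarray(tree_subset, dtype=int)
        if subset.size == 0:
            raise ValueError("tree_subset must not be empty")
        if subset.min() < 0 or subset.max() >= len(self.trees_):
            raise ValueError("tree_subset index out of range")
        return per_tree[subset].mean(axis=0)

    def oob_subforest(self, i: int) -> np.ndarray:
        """Indices of the trees whose bootstrap resample excluded row i."""
        check_is_fitted(self, "bootstrap_membership_")
        if not 0 <= i < self.n_samples_:
            raise ValueError(f"row index {i} out of range [0, {self.n_samples_})")
        return np.where(~self.bootstrap_membership_[i])[0]

    def oob_scores(self, X_train) -> np.ndarray:
        """Per-row score from each row's own sub-forest.

        ``X_train`` must be the training matrix in training row order. Rows
        that are in-bag for every tree get NaN.
        """
        per_tree = self.tree_scores(X_train)  # (T, n)
        oob_mask = (~self.bootstrap_membership_).T.astype(float)  # (T, n)
        denom = oob_mask.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(
                denom > 0, (per_tree * oob_mask).sum(axis=0) / denom, np.nan
            )

    # -- persistence ------------------------------------------------------

    _ARCHIVE_VERSION = 1

    def save(self, path: str) -> None:
        """Versioned archive: hyperparameters, trees, membership table."""
        check_is_fitted(self, "trees_")
        payload = {
            "version": self._ARCHIVE_VERSION,
            "params": self.get_params(),
            "trees": self.trees_,
            "bootstrap_counts": self.bootstrap_counts_,
            "n_features_in": self.n_features_in_,
            "n_samples": self.n_samples_,
            "mtry": self.mtry_,
            "min_node_size": self.min_node_size_,
            "classes": self.classes_,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "BootstrapForest":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != cls._ARCHIVE_VERSION:
            raise ValueError(
                f"unsupported forest archive version {payload.get('version')!r}"
            )
        forest = cls(**payload["params"])
        forest.trees_ = payload["trees"]
        forest.bootstrap_counts_ = payload["bootstrap_counts"]
        forest.bootstrap_membership_ = forest.bootstrap_counts_ > 0
        forest.n_features_in_ = payload["n_features_in"]
        forest.n_samples_ = payload["n_samples"]
        forest.mtry_ = payload["mtry"]
        forest.min_node_size_ = payload["min_node_size"]
        forest.classes_ = payload["classes"]
        return forest
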