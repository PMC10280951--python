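"""Readers/writers for feature tables, groupings, results, and run configs.

The feature-table format is a plain CSV with a mandatory header (feature
names plus one 0/1 outcome column), no index column, UTF-8. Missing values
are an error by default — imputation happens upstream of this package —
with an opt-in policy to drop incomplete rows with a count. JSON results
embed the package version, the full run configuration and its hash for
provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import Dataset
from .grouping import GroupingScheme

__all__ = ["RunConfig", "read_dataset", "read_grouping", "write_results"]


@dataclass
class RunConfig:
    """One run's knobs; round-trips losslessly through a single YAML document."""

    seed: int = 0
    n_trees: int = 500
    test_fraction: float = 0.2
    k_folds: int = 10
    threshold: float | str = "auto"
    s_rule: str = "equi"
    shrinkage: float | str = "auto"
    replicates: int = 1
    n_repeats: int = 5
    mtry: int | None = None
    min_node_size: int | None = None
    out: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_trees < 1 or self.k_folds < 2 or self.replicates < 1:
            raise ValueError("n_trees >= 1, k_folds >= 2, replicates >= 1 required")
        if self.threshold != "auto" and not 0.0 <= float(self.threshold) <= 1.0:
            raise ValueError("threshold must be 'auto' or in [0, 1]")
        if self.s_rule not in ("equi", "sdp"):
            raise ValueError("s_rule must be 'equi' or 'sdp'")

    def to_yaml(self, path: str | None = None) -> str:
        doc = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_yaml(cls, source: str) -> "RunConfig":
        import os

        if os.path.exists(source):
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(source)
        return cls(**raw)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def read_dataset(
    path: str, outcome_col: str = "outcome", missing: str = "error"
) -> Dataset:
    """Load a CSV feature table with a binary outcome column.

    ``missing="error"`` rejects any incomplete row; ``"drop"`` removes them
    and records the count in ``meta``. Non-numeric cells and outcome values
    outside {0, 1} are always errors.
    """
    df = pd.read_csv(path)
    if outcome_col not in df.columns:
        raise ValueError(f"outcome column {outcome_col!r} not found in {path}")
    bad_cols = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().sum() > df[col].isna().sum():
            bad_cols.append(col)
        df[col] = coerced
    if bad_cols:
        raise ValueError(f"non-numeric cells in column(s): {bad_cols}")
    incomplete = df.isna().any(axis=1)
    n_bad = int(incomplete.sum())
    if n_bad:
        if missing == "error":
            raise ValueError(
                f"{n_bad} row(s) contain missing values; impute upstream or "
                "pass missing='drop'"
            )
        if missing != "drop":
            raise ValueError("missing policy must be 'error' or 'drop'")
        df = df[~incomplete]
    outcome = df[outcome_col].to_numpy()
    bad_vals = sorted(float(v) for v in set(np.unique(outcome)) - {0, 1})
    if bad_vals:
        raise ValueError(
            f"outcome column {outcome_col!r} has values outside {{0, 1}}: {bad_vals}"
        )
    feats = df.drop(columns=[outcome_col])
    ds = Dataset(
        features=feats.to_numpy(dtype=float),
        feature_names=list(feats.columns),
        outcome=outcome.astype(int),
        meta={"source": str(path), "rows_dropped": n_bad},
    )
    return ds


def read_grouping(path: str, dataset: Dataset | None = None) -> GroupingScheme:
    """Load a YAML/JSON grouping and validate it (against a dataset if given)."""
    scheme = GroupingScheme.from_yaml(path)  # YAML superset covers JSON
    if dataset is not None:
        scheme.validate(dataset.feature_names)
    return scheme


def write_results(
    table: pd.DataFrame,
    path: str,
    format: str = "tsv",
    config: RunConfig | None = None,
    fig_view: bool = False,
) -> None:
    """Write a VIMP table as TSV or provenance-carrying JSON.

    ``fig_view=True`` restricts the output to rows where both VIMP_sens and
    VIMP_spec are strictly positive (the interpretability filter used when
    plotting grouped results).
    """
    if table.empty:
        raise ValueError("refusing to write an empty results table")
    if fig_view:
        from .knockoff_importance import fig_filter

        table = fig_filter(table)
    if format == "tsv":
        table.to_csv(path, sep="\t", index=False)
    elif format == "json":
        doc = {
            "package": "knockvimp",
            "version": __version__,
            "config": asdict(config) if config is not None else None,
            "config_hash": config.hash() if config is not None else None,
            "results": json.loads(table.to_json(orient="records")),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError("format must be 'tsv' or 'json'")
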