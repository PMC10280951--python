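"""Named feature groupings (domain hierarchies) for grouped importance.

A :class:`GroupingScheme` holds one or more *levels*; each level is an
ordered map from group name to a list of member feature names. Levels play
the role of progressively finer domain hierarchies (broad constructs at
level 1 down to individual measures), and every group at every level is
tested for conditional importance independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import yaml

__all__ = ["GroupingScheme"]


@dataclass
class GroupingScheme:
    """Named levels of named, non-overlapping feature groups.

    Parameters
    ----------
    levels : dict
        ``{level_name: {group_name: [feature, ...], ...}, ...}``. Within a
        single level, groups must be pairwise disjoint and non-empty.
    """

    levels: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def validate(self, feature_names: list[str] | None = None) -> None:
        """Check structural invariants, optionally against a dataset.

        Raises ``ValueError`` on an empty group, a feature repeated within
        one level, or (when ``feature_names`` is given) a group member that
        is not a dataset feature; the message lists every offender.
        """
        known = set(feature_names) if feature_names is not None else None
        for level_name, groups in self.levels.items():
            seen: dict[str, str] = {}
            unknown: list[str] = []
            for group_name, members in groups.items():
                if not members:
                    raise ValueError(
                        f"group {group_name!r} in level {level_name!r} is empty"
                    )
                for feat in members:
                    if feat in seen:
                        raise ValueError(
                            f"feature {feat!r} appears in both {seen[feat]!r} and "
                            f"{group_name!r} within level {level_name!r}"
                        )
                    seen[feat] = group_name
                    if known is not None and feat not in known:
                        unknown.append(feat)
            if unknown:
                raise ValueError(
                    f"level {level_name!r} names features absent from the "
                    f"dataset: {sorted(set(unknown))}"
                )

    def iter_groups(self) -> Iterator[tuple[str, str, list[str]]]:
        """Yield ``(level_name, group_name, members)`` in declaration order."""
        for level_name, groups in self.levels.items():
            for group_name, members in groups.items():
                yield level_name, group_name, list(members)

    @property
    def n_groups(self) -> int:
        return sum(len(groups) for groups in self.levels.values())

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path: str | None = None) -> str:
        doc = yaml.safe_dump(
            {"levels": {lv: {g: list(m) for g, m in gs.items()}
                        for lv, gs in self.levels.items()}},
            sort_keys=False,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_yaml(cls, source: str) -> "GroupingScheme":
        """Parse from a YAML document string or a path to one."""
        import os

        if os.path.exists(source):
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(source)
        if not isinstance(raw, dict) or "levels" not in raw:
            raise ValueError("grouping document must have a top-level 'levels' map")
        levels = {
            str(lv): {str(g): [str(f) for f in members]
                      for g, members in groups.items()}
            for lv, groups in raw["levels"].items()
        }
        scheme = cls(levels=levels)
        scheme.validate()
        return scheme
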