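"""Column-role declarations for a cohort table.

A cohort CSV is a flat table with one row per participant.  Which columns
are binary outcomes, which are protected attributes (gender, race, ...)
and which are predictors is declared separately in a :class:`ColumnRoles`
object, persisted as a small YAML file next to the CSV.  Protected
attributes may double as predictors — demographic variables typically
enter clinical risk models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml


@dataclass
class ColumnRoles:
    """Partition of cohort columns into outcomes, protected attributes and
    predictors.

    Parameters
    ----------
    outcome_columns : list of str
        Binary (0/1) event indicator columns.
    protected_columns : list of str
        Categorical demographic columns over whose subgroups fairness is
        evaluated.  May overlap with ``predictor_columns``.
    predictor_columns : list of str
        Model input columns, numeric or categorical.
    categorical_levels : dict
        Ordered level list per categorical predictor.  The first listed
        level is the reference level under dummy coding.  Numeric
        predictors are simply absent from this mapping.
    """

    outcome_columns: list[str]
    protected_columns: list[str]
    predictor_columns: list[str]
    categorical_levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.outcome_columns) & set(self.predictor_columns):
            raise ValueError(
                "outcome_columns and predictor_columns must be disjoint: "
                f"{sorted(set(self.outcome_columns) & set(self.predictor_columns))}"
            )
        if set(self.outcome_columns) & set(self.protected_columns):
            raise ValueError("outcome_columns and protected_columns must be disjoint")
        for name, levels in self.categorical_levels.items():
            if name not in self.predictor_columns:
                raise ValueError(
                    f"categorical_levels declares {name!r} which is not a predictor column"
                )
            if len(levels) < 2:
                raise ValueError(
                    f"categorical predictor {name!r} needs >= 2 levels, got {levels!r}"
                )
            if len(set(levels)) != len(levels):
                raise ValueError(f"duplicate levels for categorical predictor {name!r}")

    @property
    def numeric_predictors(self) -> list[str]:
        return [c for c in self.predictor_columns if c not in self.categorical_levels]

    @property
    def categorical_predictors(self) -> list[str]:
        return [c for c in self.predictor_columns if c in self.categorical_levels]

    @property
    def role_columns(self) -> list[str]:
        """All columns carrying a role, without duplicates, in declaration order."""
        seen: dict[str, None] = {}
        for c in self.outcome_columns + self.protected_columns + self.predictor_columns:
            seen.setdefault(c)
        return list(seen)

    # -- persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "outcome_columns": list(self.outcome_columns),
            "protected_columns": list(self.protected_columns),
            "predictor_columns": list(self.predictor_columns),
            "categorical_levels": {k: list(v) for k, v in self.categorical_levels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnRoles":
        return cls(
            outcome_columns=list(d["outcome_columns"]),
            protected_columns=list(d["protected_columns"]),
            predictor_columns=list(d["predictor_columns"]),
            categorical_levels={k: list(v) for k, v in d.get("categorical_levels", {}).items()},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ColumnRoles":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
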