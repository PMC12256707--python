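"""Preprocessing pipeline: complete-case filtering, reference-coded dummy
encoding, train/test split, and inverse-frequency class weights.

Complete-case analysis (no imputation) is deliberate: rows with any missing
role column are dropped.  Categorical predictors are dummy-coded with k-1
indicator columns against the first listed level, so a single coefficient
like ``gender=women`` reads as the effect relative to the reference group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .roles import ColumnRoles

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "SplitIndices",
    "drop_incomplete",
    "encode_one_hot",
    "decode_one_hot",
    "split_train_test",
    "class_weights",
]


@dataclass
class DesignMatrix:
    """Fully numeric encoded predictor matrix.

    ``frame`` has one column per encoded feature (``"<feature>=<level>"``
    for indicators, the bare name for numerics); its index carries the row
    identifiers of the source cohort table.  ``feature_groups`` maps each
    original predictor to its encoded column(s), which lets explanation
    methods permute a multi-level categorical as one unit.
    """

    frame: pd.DataFrame
    feature_groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise ValueError("design matrix contains missing cells")

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class SplitIndices:
    train: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test indices overlap")


def drop_incomplete(table: CohortTable) -> CohortTable:
    """Remove rows with any missing value in an outcome, protected, or
    predictor column.  Missingness in columns with no declared role is
    ignored.  Idempotent."""
    if table.n == 0:
        raise ValueError("cohort table is empty")
    role_cols = [c for c in table.roles.role_columns if c in table.data.columns]
    keep = table.data[role_cols].notna().all(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("drop_incomplete: removed %d of %d rows", n_removed, table.n)
    out = table.data.loc[keep]
    if len(out) == 0:
        raise ValueError("all rows removed by complete-case filtering")
    return CohortTable(out, table.roles)


def encode_one_hot(table: CohortTable, roles: ColumnRoles | None = None) -> DesignMatrix:
    """Reference-coded dummy encoding of the predictor columns.

    Each categorical predictor with k declared levels yields k-1 indicator
    columns named ``"<feature>=<level>"`` (the first listed level is the
    reference); numeric predictors pass through unchanged.  A level present
    in the data but not declared raises.
    """
    roles = roles or table.roles
    df = table.data
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, list[str]] = {}
    for feat in roles.predictor_columns:
        if feat not in df.columns:
            raise ValueError(f"predictor column {feat!r} not in table")
        if feat in roles.categorical_levels:
            levels = roles.categorical_levels[feat]
            observed = set(df[feat].dropna().astype(str))
            unseen = observed - set(map(str, levels))
            if unseen:
                raise ValueError(
                    f"unseen level(s) {sorted(unseen)} in categorical predictor {feat!r}"
                )
            group = []
            for level in levels[1:]:
                name = f"{feat}={level}"
                cols[name] = (df[feat].astype(str) == str(level)).to_numpy(dtype=float)
                group.append(name)
            groups[feat] = group
        else:
            cols[feat] = df[feat].to_numpy(dtype=float)
            groups[feat] = [feat]
    frame = pd.DataFrame(cols, index=df.index)
    return DesignMatrix(frame, groups)


def decode_one_hot(X: DesignMatrix, feature: str, levels: list[str]) -> pd.Series:
    """Invert the dummy coding of one categorical predictor (round trip)."""
    out = pd.Series(levels[0], index=X.frame.index, dtype=object)
    for level in levels[1:]:
        name = f"{feature}={level}"
        out[X.frame[name] == 1.0] = level
    return out


def split_train_test(n_rows: int, fraction: float = 0.7, seed: int = 0) -> SplitIndices:
    """Unstratified random partition; train size is round-half-up of
    fraction * n (e.g. 9635 rows at 0.7 -> 6745 train / 2890 test)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if n_rows < 2:
        raise ValueError(f"need at least 2 rows to split, got {n_rows}")
    n_train = int(np.floor(fraction * n_rows + 0.5))
    if n_train == 0 or n_train == n_rows:
        raise ValueError(f"degenerate split: train size {n_train} of {n_rows}")
    perm = np.random.default_rng(seed).permutation(n_rows)
    return SplitIndices(train=np.sort(perm[:n_train]), test=np.sort(perm[n_train:]), seed=seed)


def class_weights(labels) -> dict[int, float]:
    """Balanced inverse-frequency weights: w(c) = n_total / (2 * n_c).

    Multiplied into the per-sample loss during fitting, these equalise the
    aggregate weight of the two classes (important here: 5-year MI/stroke
    events are rare)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("class_weights requires both classes present")
    if len(classes) > 2 or not set(classes.tolist()) <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got classes {classes.tolist()}")
    n = len(y)
    return {int(c): n / (2.0 * cnt) for c, cnt in zip(classes, counts)}
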