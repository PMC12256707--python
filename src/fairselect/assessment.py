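"""Stage 1 — model assessment: discrimination, threshold metrics, and the
relative performance parity score (RPPS).

Predictive performance is summarised by AUC plus sensitivity, specificity
and accuracy at an operating threshold chosen to maximise
``u * sensitivity + (1 - u) * specificity`` (default u = 2/3, leaning
toward sensitivity: missing a true cardiovascular event is costlier than a
false alarm).

Fairness is summarised per protected attribute by subgroup-conditional
AUCs and the relative performance parity score

    RPPS = 1 - max_s |AUC_s - AUC| / AUC,

the largest relative deviation of any subgroup's AUC from the overall AUC,
subtracted from 1.  RPPS = 1 means every subgroup matches the overall AUC;
the score is threshold-free and, being relative to each model's own AUC,
comparable across models.  It is not clamped below: a subgroup deviating
by more than the overall AUC gives a negative score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ThresholdCriterion",
    "PerformanceReport",
    "GroupLabels",
    "FairnessReport",
    "roc_auc",
    "optimize_threshold",
    "confusion_metrics",
    "subgroup_auc",
    "rpps",
    "assess_model",
    "reports_to_frame",
]


@dataclass(frozen=True)
class ThresholdCriterion:
    """Sensitivity weight u in the objective u*sens + (1-u)*spec."""

    u: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.u <= 1.0):
            raise ValueError(f"u must be in [0, 1], got {self.u}")


@dataclass
class PerformanceReport:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    criterion: ThresholdCriterion


@dataclass
class GroupLabels:
    """Per-row subgroup membership for one protected attribute."""

    attribute: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)


@dataclass
class FairnessReport:
    attribute: str
    overall_auc: float
    subgroup_aucs: dict[str, float]
    rpps: float
    unevaluable: list[str] = field(default_factory=list)


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if not set(np.unique(y).tolist()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y


def roc_auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative, ties 1/2.

    Rank-statistic (Mann-Whitney) form; identical to the trapezoidal area
    under the ROC curve.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_metrics(scores, labels, threshold: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) under the ``score >= t`` rule."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean())
    spec = float((~pred[neg]).mean())
    acc = float((pred == (y == 1)).mean())
    return sens, spec, acc


def optimize_threshold(
    scores, labels, criterion: ThresholdCriterion = ThresholdCriterion()
) -> tuple[float, PerformanceReport]:
    """Pick the observed score maximizing u*sens + (1-u)*spec as threshold.

    Candidate thresholds are the unique observed scores (prediction rule:
    positive iff score >= t).  Objective ties break toward the lower
    threshold, i.e. higher sensitivity.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    u = criterion.u
    candidates = np.unique(s)  # sorted ascending
    best_t, best_obj = None, -np.inf
    for t in candidates:
        sens, spec, _ = confusion_metrics(s, y, t)
        obj = u * sens + (1.0 - u) * spec
        if obj > best_obj + 1e-12:  # strict improvement; ties keep lower t
            best_obj, best_t = obj, float(t)
    sens, spec, acc = confusion_metrics(s, y, best_t)
    report = PerformanceReport(
        auc=roc_auc(s, y), sensitivity=sens, specificity=spec, accuracy=acc,
        threshold=best_t, criterion=criterion,
    )
    return best_t, report


def subgroup_auc(scores, labels, groups: GroupLabels) -> tuple[dict[str, float], list[str]]:
    """Conditional AUC per subgroup of a protected attribute.

    Returns (aucs, unevaluable): a subgroup whose rows carry only one
    outcome class cannot yield an AUC; it is reported in ``unevaluable``
    (and excluded from the RPPS max) with a warning rather than failing
    the whole report.  Empty subgroups simply do not appear.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    g = groups.labels
    if not (len(y) == len(s) == len(g)):
        raise ValueError("scores, labels, and group labels must align")
    aucs: dict[str, float] = {}
    unevaluable: list[str] = []
    for level in pd.unique(pd.Series(g)):
        mask = g == level
        if not mask.any():
            continue
        if len(np.unique(y[mask])) < 2:
            warnings.warn(
                f"subgroup {level!r} of {groups.attribute!r} has a single outcome class; "
                "excluded from RPPS",
                stacklevel=2,
            )
            unevaluable.append(str(level))
            continue
        aucs[str(level)] = roc_auc(s[mask], y[mask])
    return aucs, unevaluable


def rpps(overall_auc: float, subgroup_aucs: dict[str, float]) -> float:
    """1 minus the largest relative deviation of any subgroup AUC from the
    overall AUC.  Not clamped: may be negative under extreme disparity."""
    if overall_auc <= 0:
        raise ValueError(f"overall_auc must be > 0, got {overall_auc}")
    if not subgroup_aucs:
        raise ValueError("subgroup_aucs is empty")
    max_dev = max(abs(a - overall_auc) for a in subgroup_aucs.values())
    return 1.0 - max_dev / overall_auc


def assess_model(
    model,
    X,
    y,
    protected: list[GroupLabels],
    criterion: ThresholdCriterion = ThresholdCriterion(),
) -> tuple[PerformanceReport, list[FairnessReport]]:
    """Full stage-1 assessment of one fitted model on held-out data.

    The threshold-dependent metrics use the u-optimized operating point;
    the fairness reports are threshold-free (AUC-based), one per protected
    attribute.
    """
    scores = model.risk_scores(X)
    _, perf = optimize_threshold(scores, y, criterion)
    fairness = []
    for groups in protected:
        aucs, bad = subgroup_auc(scores, y, groups)
        fairness.append(
            FairnessReport(
                attribute=groups.attribute,
                overall_auc=perf.auc,
                subgroup_aucs=aucs,
                rpps=rpps(perf.auc, aucs),
                unevaluable=bad,
            )
        )
    return perf, fairness


def reports_to_frame(
    results: dict[str, tuple[PerformanceReport, list[FairnessReport]]]
) -> pd.DataFrame:
    """Flatten assessment results into one row per model: the four
    performance metrics and threshold, then per (attribute, subgroup) AUC
    and per-attribute RPPS."""
    rows = []
    for name, (perf, fairness) in results.items():
        row: dict[str, float | str] = {
            "model": name,
            "auc": perf.auc,
            "sensitivity": perf.sensitivity,
            "specificity": perf.specificity,
            "accuracy": perf.accuracy,
            "threshold": perf.threshold,
        }
        for fr in fairness:
            for level, auc_s in fr.subgroup_aucs.items():
                row[f"auc[{fr.attribute}={level}]"] = auc_s
            row[f"rpps[{fr.attribute}]"] = fr.rpps
        rows.append(row)
    return pd.DataFrame(rows)
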