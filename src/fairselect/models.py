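"""Model zoo: one adapter contract over all candidate binary classifiers.

Downstream stages (assessment, selection, explanation) are model-agnostic;
they only ever see a :class:`FittedModel`, which promises risk scores in
[0, 1] and log-odds margins.  The candidate families cover the usual
clinical-tabular suspects: penalized logistic regression, greedy decision
trees at depth 3-4 (an interpretable stand-in for mixed-integer optimal
trees), random forests, gradient boosting, Gaussian naive Bayes, and an
RBF SVM whose decision values are converted to probabilities by Platt
scaling inside the adapter so the risk contract holds for every family.

Hyperparameters are tuned by maximizing mean 10-fold cross-validated AUC
over a declared grid, then refitting on the full training matrix, with
per-sample class weights applied throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ._util import clamped_logit
from .preprocess import DesignMatrix

__all__ = ["ModelSpec", "FittedModel", "tune_and_fit", "FAMILIES", "default_model_specs"]

FAMILIES = (
    "penalized-logistic",
    "decision-tree",
    "random-forest",
    "gradient-boosting",
    "naive-bayes",
    "svm",
)


@dataclass
class ModelSpec:
    """A classifier family plus its hyperparameter search grid."""

    family: str
    grid: dict[str, list[Any]] = field(default_factory=dict)
    class_weights: dict[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        for name, values in self.grid.items():
            if not isinstance(values, (list, tuple)) or len(values) == 0:
                raise ValueError(f"grid entry {name!r} must be a nonempty list")

    def grid_points(self) -> list[dict[str, Any]]:
        """All grid combinations in deterministic declaration order."""
        if not self.grid:
            return [{}]
        names = list(self.grid)
        return [dict(zip(names, combo)) for combo in itertools.product(*(self.grid[n] for n in names))]


def _build_estimator(family: str, params: dict[str, Any], seed: int):
    if family == "penalized-logistic":
        # standardize inside the estimator (as glmnet does internally) so the
        # elastic-net penalty is scale-free and saga converges quickly;
        # linear_coefficients back-transforms to the raw encoded scale
        defaults: dict[str, Any] = dict(solver="saga", l1_ratio=0.5, C=1.0, max_iter=5000)
        defaults.update(params)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(random_state=seed, **defaults)),
            ]
        )
    if family == "decision-tree":
        defaults = dict(max_depth=4, min_samples_leaf=20)
        defaults.update(params)
        return DecisionTreeClassifier(random_state=seed, **defaults)
    if family == "random-forest":
        defaults = dict(n_estimators=200, min_samples_leaf=5, n_jobs=1)
        defaults.update(params)
        return RandomForestClassifier(random_state=seed, **defaults)
    if family == "gradient-boosting":
        defaults = dict(
            n_estimators=150, max_depth=3, learning_rate=0.1, n_jobs=1,
            eval_metric="logloss", tree_method="hist",
        )
        defaults.update(params)
        return XGBClassifier(random_state=seed, **defaults)
    if family == "naive-bayes":
        return GaussianNB(**params)
    if family == "svm":
        defaults = dict(kernel="rbf", C=1.0, gamma="scale")
        defaults.update(params)
        # Platt-style sigmoid calibration of decision values -> probabilities
        return CalibratedClassifierCV(
            SVC(random_state=seed, **defaults), method="sigmoid", ensemble=False, cv=5
        )
    raise ValueError(f"unknown family {family!r}")


@dataclass
class FittedModel:
    """Uniform adapter around a fitted binary classifier.

    Guarantees: :meth:`risk_scores` lies in [0, 1] and
    :meth:`margin_scores` equals logit(risk) with risk clamped to
    [1e-12, 1 - 1e-12], so risk and margin are a bijection on (0, 1).
    """

    family: str
    params: dict[str, Any]
    estimator: Any
    feature_names: list[str]

    def _check_columns(self, X: DesignMatrix) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                f"design-matrix columns {list(X.columns)} do not match "
                f"training columns {self.feature_names}"
            )
        arr = X.values
        if arr.shape[1] == 0:  # intercept-only model trained on a dummy column
            arr = np.zeros((arr.shape[0], 1))
        return arr

    def risk_scores(self, X: DesignMatrix) -> np.ndarray:
        """Per-row event probability in [0, 1]."""
        arr = self._check_columns(X)
        proba = self.estimator.predict_proba(arr)
        pos = list(self.estimator.classes_).index(1)
        return np.clip(proba[:, pos].astype(np.float64), 0.0, 1.0)

    def margin_scores(self, X: DesignMatrix) -> np.ndarray:
        """Log-odds of the risk score (clamped so the transform is finite)."""
        return clamped_logit(self.risk_scores(X))

    def linear_coefficients(self) -> tuple[dict[str, float], float]:
        """Fitted coefficients on the encoded feature space (penalized
        logistic only); features shrunk to zero are reported as 0."""
        if self.family != "penalized-logistic":
            raise ValueError(
                f"linear_coefficients is only defined for penalized-logistic, not {self.family!r}"
            )
        clf = self.estimator.named_steps["clf"]
        intercept = float(np.ravel(clf.intercept_)[0])
        if not self.feature_names:
            return {}, intercept
        scaler = self.estimator.named_steps["scale"]
        beta_std = np.ravel(clf.coef_)
        scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
        beta_raw = beta_std / scale
        intercept -= float(np.sum(beta_std * scaler.mean_ / scale))
        return {name: float(b) for name, b in zip(self.feature_names, beta_raw)}, intercept


def _fit(est, X, y, sample_weight=None):
    if sample_weight is None:
        est.fit(X, y)
    elif isinstance(est, Pipeline):
        est.fit(X, y, clf__sample_weight=sample_weight)
    else:
        est.fit(X, y, sample_weight=sample_weight)
    return est


def _roc_auc_safe(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    from .assessment import roc_auc  # local import avoids a cycle

    if len(np.unique(y_true)) < 2:
        return None
    return roc_auc(scores, y_true)


def tune_and_fit(spec: ModelSpec, X: DesignMatrix, y) -> FittedModel:
    """Pick the grid point maximizing mean 10-fold CV AUC, refit on all data.

    Folds are an unstratified random partition, deterministic given
    ``spec.seed``; sample weights from ``spec.class_weights`` are applied
    in every fit.  Ties between grid points go to the earlier point in
    declaration order.
    """
    y = np.asarray(y)
    arr = X.values
    if arr.shape[1] == 0:  # intercept-only: fit against an all-zero dummy column
        arr = np.zeros((arr.shape[0], 1))
    if len(np.unique(y)) < 2:
        raise ValueError("tune_and_fit requires both classes present in y")
    n_folds = 10
    if len(y) < n_folds:
        raise ValueError(f"need at least {n_folds} rows for {n_folds}-fold CV, got {len(y)}")
    sw = None
    if spec.class_weights is not None:
        sw = np.asarray([spec.class_weights[int(c)] for c in y], dtype=float)

    points = spec.grid_points()
    best_point, best_auc = None, -np.inf
    if len(points) == 1:
        best_point = points[0]
    else:
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
        folds = list(kf.split(arr))
        for point in points:
            aucs = []
            for tr, va in folds:
                if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                    continue
                est = _build_estimator(spec.family, point, spec.seed)
                _fit(est, arr[tr], y[tr], None if sw is None else sw[tr])
                pos = list(est.classes_).index(1)
                auc = _roc_auc_safe(y[va], est.predict_proba(arr[va])[:, pos])
                if auc is not None:
                    aucs.append(auc)
            if not aucs:
                raise ValueError("no CV fold had both classes in train and validation")
            mean_auc = float(np.mean(aucs))
            if mean_auc > best_auc + 1e-12:
                best_auc, best_point = mean_auc, point

    est = _build_estimator(spec.family, best_point, spec.seed)
    _fit(est, arr, y, sw)
    return FittedModel(spec.family, dict(best_point), est, list(X.columns))


def default_model_specs(class_weights: dict[int, float] | None, seed: int) -> dict[str, ModelSpec]:
    """The default candidate set: one spec per family, small tuning grids."""
    return {
        "logistic-en": ModelSpec(
            "penalized-logistic", {"C": [0.1, 1.0], "l1_ratio": [0.2, 0.8]},
            class_weights, seed,
        ),
        "tree-d34": ModelSpec("decision-tree", {"max_depth": [3, 4]}, class_weights, seed),
        "random-forest": ModelSpec("random-forest", {"min_samples_leaf": [5, 20]}, class_weights, seed),
        "xgboost": ModelSpec("gradient-boosting", {"max_depth": [2, 3]}, class_weights, seed),
        "naive-bayes": ModelSpec("naive-bayes", {}, class_weights, seed),
        "svm-rbf": ModelSpec("svm", {"C": [1.0]}, class_weights, seed),
    }
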