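"""Stage 3 — the synergistic explanation layer.

Three complementary views of a fitted classifier are combined:

* **Bootstrapped permutation importance** — per bootstrap replicate the
  training rows are resampled, the model is refit, a baseline AUC is
  computed on the out-of-bag rows, and each predictor's columns are
  shuffled to record the AUC drop.  Means and percentile confidence
  intervals over replicates quantify both importance and its stability;
  negative values are reported as-is (they typically flag predictors the
  model fit to noise).

* **Shapley values** — per-row additive attributions on the margin
  (log-odds) scale with the training set as interventional background.
  For linear margin models the closed form phi_i = beta_i (x_i - E[x_i])
  is exact; otherwise a permutation-sampling estimator is used, with the
  base value estimated from the same sampled background rows so the
  efficiency identity sum_i phi_i + base = margin(x) holds exactly row by
  row.  *Relative* Shapley values divide each row by its total
  attribution, so contributions sum to 1 per row and are comparable
  across individuals.

* **Partial dependence** — mean model output (risk and log-odds) as one
  encoded feature is swept over its observed range with all other
  features held at their observed values, plus a histogram of the
  feature's data density so sparsely supported regions are visible.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import spawn_seed
from .assessment import roc_auc
from .models import FittedModel, ModelSpec, tune_and_fit
from .preprocess import DesignMatrix

__all__ = [
    "ExplainConfig",
    "ImportanceTable",
    "ShapMatrix",
    "RelativeShapMatrix",
    "PDPCurve",
    "bootstrap_permutation_importance",
    "shapley_linear_exact",
    "shapley_sampling",
    "relative_shapley",
    "partial_dependence",
    "explain_model",
    "refit_procedure",
]


@dataclass
class ExplainConfig:
    n_bootstrap: int = 100
    permutations_per_feature: int = 1
    ci_level: float = 0.95
    shapley_samples: int = 64
    pdp_grid_size: int = 50
    top_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        for name in ("n_bootstrap", "permutations_per_feature", "shapley_samples",
                     "pdp_grid_size", "top_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ImportanceTable:
    """Per-feature mean AUC drop with percentile bootstrap CI and rank."""

    table: pd.DataFrame  # columns: feature, mean, ci_lo, ci_hi, rank
    n_replicates_used: int

    def top_features(self, k: int) -> list[str]:
        return self.table.sort_values("rank")["feature"].head(k).tolist()


@dataclass
class ShapMatrix:
    """Per (row, feature) Shapley values on the margin scale.

    ``values`` rows sum (plus ``base``) to the model's margin for each row;
    ``se`` is the per-cell Monte-Carlo standard error (zeros for the exact
    and exhaustive paths).
    """

    values: pd.DataFrame
    base: float
    se: pd.DataFrame | None = None
    scale: str = "margin"


@dataclass
class RelativeShapMatrix:
    """Shapley values normalized by each row's total attribution."""

    values: pd.DataFrame  # NaN on degenerate rows
    valid: np.ndarray
    summary: pd.Series  # per-feature mean of relative values over valid rows


@dataclass
class PDPCurve:
    feature: str
    grid: np.ndarray
    mean_risk: np.ndarray
    mean_margin: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def refit_procedure(model: FittedModel, class_weights: dict[int, float] | None = None):
    """A deterministic fit procedure that retrains the given model's family
    at its chosen hyperparameters (singleton grid) — the refitting engine
    for bootstrapped permutation importance."""

    def fit(X: DesignMatrix, y, seed: int) -> FittedModel:
        spec = ModelSpec(
            model.family,
            {k: [v] for k, v in model.params.items()},
            class_weights,
            seed,
        )
        return tune_and_fit(spec, X, y)

    return fit


def bootstrap_permutation_importance(
    fit_procedure, X: DesignMatrix, y, config: ExplainConfig
) -> ImportanceTable:
    """Bootstrap-refit permutation importance with percentile CIs.

    For each of ``config.n_bootstrap`` replicates: resample rows with
    replacement, refit via ``fit_procedure(X_b, y_b, seed_b)``, compute a
    baseline AUC on the out-of-bag rows, then for every original predictor
    permute its encoded column block (jointly, so a multi-level categorical
    is shuffled as one unit) and record baseline minus permuted AUC.
    Replicates whose out-of-bag rows carry a single outcome class are
    skipped with a warning; if more than half are skipped the estimate is
    refused.
    """
    y = np.asarray(y)
    n = len(y)
    features = list(X.feature_groups)
    records = {f: [] for f in features}
    n_used = 0
    for b in range(config.n_bootstrap):
        rng = np.random.default_rng(spawn_seed(config.seed, 10_000 + b))
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0 or len(np.unique(y[oob])) < 2:
            warnings.warn(f"replicate {b}: out-of-bag rows single-class; skipped", stacklevel=2)
            continue
        Xb = DesignMatrix(X.frame.iloc[idx].reset_index(drop=True), X.feature_groups)
        model = fit_procedure(Xb, y[idx], spawn_seed(config.seed, 20_000 + b))
        oob_frame = X.frame.iloc[oob].reset_index(drop=True)
        y_oob = y[oob]
        baseline = roc_auc(
            model.risk_scores(DesignMatrix(oob_frame, X.feature_groups)), y_oob
        )
        for feat in features:
            cols = X.feature_groups[feat]
            if oob_frame[cols].nunique().le(1).all():
                records[feat].append(0.0)  # permuting a constant is the identity
                continue
            drops = []
            for _ in range(config.permutations_per_feature):
                perm = rng.permutation(len(oob_frame))
                shuffled = oob_frame.copy()
                shuffled[cols] = oob_frame[cols].to_numpy()[perm]
                auc_p = roc_auc(
                    model.risk_scores(DesignMatrix(shuffled, X.feature_groups)), y_oob
                )
                drops.append(baseline - auc_p)
            records[feat].append(float(np.mean(drops)))
        n_used += 1
    if n_used < config.n_bootstrap / 2.0:
        raise ValueError(
            f"only {n_used}/{config.n_bootstrap} bootstrap replicates usable "
            "(out-of-bag rows single-class too often)"
        )
    alpha = 1.0 - config.ci_level
    rows = []
    for feat in features:
        vals = np.asarray(records[feat])
        rows.append(
            {
                "feature": feat,
                "mean": float(vals.mean()),
                "ci_lo": float(np.percentile(vals, 100 * alpha / 2)),
                "ci_hi": float(np.percentile(vals, 100 * (1 - alpha / 2))),
            }
        )
    table = pd.DataFrame(rows)
    table["rank"] = table["mean"].rank(ascending=False, method="first").astype(int)
    return ImportanceTable(table, n_used)


def shapley_linear_exact(
    coefficients: dict[str, float], intercept: float, X: DesignMatrix, background: DesignMatrix
) -> ShapMatrix:
    """Exact interventional Shapley values for a linear margin model:
    phi_i(x) = beta_i * (x_i - mean background x_i); the base value is the
    margin at the background mean."""
    if len(background) == 0:
        raise ValueError("background is empty")
    beta = np.array([coefficients.get(c, 0.0) for c in X.columns])
    mu = background.frame[X.columns].mean().to_numpy()
    values = (X.frame.to_numpy() - mu) * beta
    base = float(intercept + beta @ mu)
    vals = pd.DataFrame(values, index=X.frame.index, columns=X.columns)
    se = pd.DataFrame(0.0, index=X.frame.index, columns=X.columns)
    return ShapMatrix(vals, base, se)


def shapley_sampling(
    model: FittedModel, X: DesignMatrix, background: DesignMatrix, config: ExplainConfig
) -> ShapMatrix:
    """Permutation-sampling estimator of interventional Shapley values on
    the margin scale.

    Each iteration draws a feature ordering and a background row, then
    walks the ordering replacing background values with the explained
    row's values; a feature's contribution is the change in margin when it
    is switched in.  Contributions telescope, so with the base value taken
    as the mean margin of the *sampled* background rows, efficiency
    (sum phi = margin - base) holds exactly for every row.  When the
    sample budget covers all (ordering, background-row) pairs the
    enumeration is exhaustive and the estimate is exact.
    """
    if len(background) == 0:
        raise ValueError("background is empty")
    cols = X.columns
    d = len(cols)
    n = len(X)
    rng = np.random.default_rng(spawn_seed(config.seed, 77))
    n_bg = len(background)
    total_pairs = math.factorial(d) * n_bg if d <= 10 else None
    if total_pairs is not None and total_pairs <= config.shapley_samples:
        pairs = [
            (list(p), zi)
            for p in itertools.permutations(range(d))
            for zi in range(n_bg)
        ]
        exhaustive = True
    else:
        pairs = [
            (list(rng.permutation(d)), int(rng.integers(0, n_bg)))
            for _ in range(config.shapley_samples)
        ]
        exhaustive = False

    x_arr = X.frame.to_numpy(dtype=float)
    bg_arr = background.frame[cols].to_numpy(dtype=float)
    contrib = np.zeros((len(pairs), n, d))
    base_samples = np.zeros(len(pairs))
    for m, (order, zi) in enumerate(pairs):
        hybrid = np.tile(bg_arr[zi], (n, 1))
        prev = model.margin_scores(DesignMatrix(pd.DataFrame(hybrid, columns=cols), X.feature_groups))
        base_samples[m] = prev[0]  # all rows identical at the pure-background point
        for j in order:
            hybrid[:, j] = x_arr[:, j]
            curr = model.margin_scores(
                DesignMatrix(pd.DataFrame(hybrid, columns=cols), X.feature_groups)
            )
            contrib[m, :, j] = curr - prev
            prev = curr
    phi = contrib.mean(axis=0)
    base = float(base_samples.mean())
    if exhaustive or len(pairs) < 2:
        se = np.zeros((n, d))
    else:
        se = contrib.std(axis=0, ddof=1) / np.sqrt(len(pairs))
    return ShapMatrix(
        pd.DataFrame(phi, index=X.frame.index, columns=cols),
        base,
        pd.DataFrame(se, index=X.frame.index, columns=cols),
    )


def relative_shapley(shap: ShapMatrix, eps: float = 1e-12) -> RelativeShapMatrix:
    """Normalize each row by its total attribution sum_j phi_j, so relative
    values sum to 1 per row.  Rows with (near-)zero total attribution are
    flagged invalid and excluded from the per-feature summary means."""
    totals = shap.values.sum(axis=1)
    valid = np.abs(totals.to_numpy()) > eps
    if not valid.any():
        raise ValueError("all rows have zero total attribution")
    rel = shap.values.div(totals, axis=0)
    rel[~valid] = np.nan
    summary = rel.loc[valid].mean(axis=0)
    return RelativeShapMatrix(rel, valid, summary)


def partial_dependence(
    model: FittedModel, X: DesignMatrix, feature: str, config: ExplainConfig = ExplainConfig()
) -> PDPCurve:
    """Partial dependence of the model output on one encoded feature.

    The grid is the feature's observed unique values when there are at
    most a handful (indicator columns get exactly their observed levels),
    else ``pdp_grid_size`` equally spaced points over the observed range.
    At each grid value v the feature column is set to v in every row and
    the model output averaged over rows — reported on both the risk scale
    and the log-odds scale (mean of per-row margins).  A histogram of the
    observed values accompanies the curve so regions of data scarcity are
    visible.
    """
    if feature not in X.frame.columns:
        raise ValueError(f"unknown feature {feature!r}")
    obs = X.frame[feature].to_numpy(dtype=float)
    uniq = np.unique(obs)
    if len(uniq) <= 2:
        grid = uniq
    else:
        grid = np.linspace(obs.min(), obs.max(), config.pdp_grid_size)
    mean_risk = np.empty(len(grid))
    mean_margin = np.empty(len(grid))
    work = X.frame.copy()
    for i, v in enumerate(grid):
        work[feature] = v
        Xi = DesignMatrix(work, X.feature_groups)
        mean_risk[i] = model.risk_scores(Xi).mean()
        mean_margin[i] = model.margin_scores(Xi).mean()
    counts, edges = np.histogram(obs, bins=min(20, max(len(uniq), 2)))
    return PDPCurve(feature, grid, mean_risk, mean_margin, counts, edges)


def explain_model(
    model: FittedModel,
    X: DesignMatrix,
    y,
    config: ExplainConfig = ExplainConfig(),
    fit_procedure=None,
    class_weights: dict[int, float] | None = None,
) -> tuple[ImportanceTable, ShapMatrix, RelativeShapMatrix, dict[str, PDPCurve]]:
    """Run the full explanation layer for one fitted model.

    Composes bootstrapped permutation importance (refitting via
    ``fit_procedure``, by default the model's own family/hyperparameters),
    Shapley values (exact closed form for the linear family, sampling
    estimator otherwise) with their relative normalization, and partial
    dependence curves for the top-k features by mean importance.
    """
    fit_procedure = fit_procedure or refit_procedure(model, class_weights)
    importance = bootstrap_permutation_importance(fit_procedure, X, y, config)
    if model.family == "penalized-logistic":
        coefs, intercept = model.linear_coefficients()
        shap = shapley_linear_exact(coefs, intercept, X, X)
    else:
        shap = shapley_sampling(model, X, X, config)
    rel = relative_shapley(shap)
    top = importance.top_features(min(config.top_k, len(X.feature_groups)))
    curves: dict[str, PDPCurve] = {}
    for feat in top:
        for col in X.feature_groups[feat]:
            curves[col] = partial_dependence(model, X, col, config)
    return importance, shap, rel, curves
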