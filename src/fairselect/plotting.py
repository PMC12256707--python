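"""Figure helpers mirroring the framework's standard visual outputs:
importance bars with CI whiskers, relative-Shapley summaries, partial
dependence with a data-density rug, and the accuracy/fairness trade-off."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .explanation import ImportanceTable, PDPCurve, RelativeShapMatrix
from .selection import TradeoffCurve


def plot_importance(imp: ImportanceTable, path) -> None:
    t = imp.table.sort_values("mean")
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(t) + 1.5))
    err = np.vstack([t["mean"] - t["ci_lo"], t["ci_hi"] - t["mean"]])
    ax.barh(t["feature"], t["mean"], xerr=err, color="steelblue", capsize=3)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Mean AUC drop (95% CI)")
    ax.set_title("Bootstrapped permutation importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_relative_shapley(rel: RelativeShapMatrix, path, max_points: int = 500) -> None:
    order = rel.summary.sort_values().index
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(order) + 1.5))
    rng = np.random.default_rng(0)
    for i, feat in enumerate(order):
        vals = rel.values[feat].dropna().to_numpy()
        if len(vals) > max_points:
            vals = rng.choice(vals, max_points, replace=False)
        ax.scatter(vals, i + rng.uniform(-0.25, 0.25, len(vals)), s=4, alpha=0.4)
        ax.scatter([rel.summary[feat]], [i], marker="|", s=300, color="red")
    ax.set_yticks(range(len(order)), order)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Relative Shapley value (red = mean)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pdp(curve: PDPCurve, path) -> None:
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(6, 5), sharex=True, height_ratios=[3, 1]
    )
    ax1.plot(curve.grid, curve.mean_margin, "-o", ms=3, color="darkorange", label="log-odds")
    ax1.set_ylabel("Mean log-odds")
    ax1b = ax1.twinx()
    ax1b.plot(curve.grid, curve.mean_risk, "--", color="steelblue", label="risk")
    ax1b.set_ylabel("Mean risk")
    ax1.set_title(f"Partial dependence: {curve.feature}")
    centers = 0.5 * (curve.hist_edges[:-1] + curve.hist_edges[1:])
    widths = np.diff(curve.hist_edges)
    ax2.bar(centers, curve.hist_counts, width=widths, color="grey", alpha=0.6)
    ax2.set_ylabel("Count")
    ax2.set_xlabel(curve.feature)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tradeoff(curve: TradeoffCurve, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    for name in curve.models:
        ax.plot(curve.grid.w_values, curve.scores.loc[name], label=name)
    for w_star, _, after in curve.crossovers:
        ax.axvline(float(w_star), color="grey", ls=":", lw=0.8)
    ax.set_xlabel("Weight w on accuracy")
    ax.set_ylabel("w·Accuracy + (1−w)·RPPS")
    ax.set_title("Accuracy–fairness trade-off")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
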