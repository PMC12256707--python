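"""Stage 2 — accuracy/fairness trade-off model selection.

Each candidate model is scored by the weighted sum

    score(w) = w * accuracy + (1 - w) * RPPS,      w in [0, 1],

so w = 1 ranks models purely by accuracy and w = 0 purely by fairness
parity.  Sweeping w yields, per model, a line in the (w, score) plane; the
best model at each w is the upper envelope of those lines.  Crossover
points between consecutive dominance regions are solved exactly as
rational line intersections rather than read off the grid, so the reported
region boundaries are not grid-snapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = ["TradeoffGrid", "TradeoffCurve", "weighted_score", "tradeoff_curve"]

_TIE_TOL = 1e-12


@dataclass
class TradeoffGrid:
    """Ordered w values in [0, 1]; endpoints 0 and 1 are required."""

    w_values: np.ndarray = field(default_factory=lambda: np.round(np.linspace(0, 1, 21), 10))

    def __post_init__(self) -> None:
        w = np.asarray(self.w_values, dtype=float)
        if len(w) == 0 or np.any(np.diff(w) <= 0):
            raise ValueError("w_values must be sorted and unique")
        if w[0] != 0.0 or w[-1] != 1.0:
            raise ValueError("w grid must include endpoints 0 and 1")
        self.w_values = w


@dataclass
class TradeoffCurve:
    models: list[str]
    accuracy: dict[str, float]
    rpps: dict[str, float]
    grid: TradeoffGrid
    scores: pd.DataFrame  # rows = models, columns = w values
    best_per_w: list[list[str]]  # all tied argmax models per grid w
    crossovers: list[tuple[Fraction, str, str]]  # (w*, model before, model after)

    def regions(self) -> list[dict]:
        """Dominance regions: contiguous w intervals with one leading model."""
        out = []
        lo = Fraction(0)
        current = self.best_per_w[0]
        for w_star, _, after in self.crossovers:
            out.append({"w_lo": float(lo), "w_hi": float(w_star), "best": current})
            lo = w_star
            current = [after]
        out.append({"w_lo": float(lo), "w_hi": 1.0, "best": self.best_per_w[-1]})
        return out


def weighted_score(accuracy: float, rpps: float, w: float) -> float:
    """w * accuracy + (1 - w) * rpps."""
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"w must be in [0, 1], got {w}")
    return w * accuracy + (1.0 - w) * rpps


def _crossover_w(a1: float, r1: float, a2: float, r2: float) -> Fraction | None:
    """Exact w where the two score lines intersect, if inside (0, 1)."""
    num = Fraction(r2) - Fraction(r1)
    den = (Fraction(a1) - Fraction(r1)) - (Fraction(a2) - Fraction(r2))
    if den == 0:
        return None
    w = num / den
    return w if 0 < w < 1 else None


def tradeoff_curve(
    models: list[tuple[str, float, float]], grid: TradeoffGrid | None = None
) -> TradeoffCurve:
    """Score every model at every w and locate the dominance regions.

    Parameters
    ----------
    models : list of (name, accuracy, rpps)
        Stage-1 outputs per candidate model.
    grid : TradeoffGrid, optional
        Defaults to w = 0, 0.05, ..., 1.

    Ties at a grid point are all reported (selection output is advisory);
    crossovers between consecutive distinct leaders are exact rationals of
    the four defining inputs.
    """
    if not models:
        raise ValueError("need at least one model")
    grid = grid or TradeoffGrid()
    names = [m[0] for m in models]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names")
    acc = {n: float(a) for n, a, _ in models}
    rp = {n: float(r) for n, _, r in models}
    for n in names:
        if not (np.isfinite(acc[n]) and np.isfinite(rp[n])):
            raise ValueError(f"non-finite inputs for model {n!r}")

    w = grid.w_values
    mat = np.array([[weighted_score(acc[n], rp[n], wi) for wi in w] for n in names])
    scores = pd.DataFrame(mat, index=names, columns=w)

    best_per_w: list[list[str]] = []
    for j in range(len(w)):
        col = mat[:, j]
        top = col.max()
        best_per_w.append([n for i, n in enumerate(names) if col[i] >= top - _TIE_TOL])

    # crossovers between consecutive grid points whose (single) leader changes
    crossovers: list[tuple[Fraction, str, str]] = []
    for j in range(1, len(w)):
        prev, curr = best_per_w[j - 1][0], best_per_w[j][0]
        if curr not in best_per_w[j - 1]:
            w_star = _crossover_w(acc[prev], rp[prev], acc[curr], rp[curr])
            if w_star is not None:
                crossovers.append((w_star, prev, curr))
    return TradeoffCurve(names, acc, rp, grid, scores, best_per_w, crossovers)
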