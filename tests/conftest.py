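"""Shared fixtures: small known-truth cohorts and stub models.

The stubs implement just the adapter contract (risk in [0,1], margin =
logit(risk)) so assessment and explanation components can be exercised
against closed-form expectations without any actual model fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from fairselect.cohort import CohortSpec, accord_like_spec, generate_cohort
from fairselect.preprocess import DesignMatrix
from fairselect._util import clamped_logit


class LinearStubModel:
    """Fixed linear-margin model: margin = intercept + X beta."""

    family = "stub-linear"
    params: dict = {}

    def __init__(self, beta: dict[str, float], intercept: float = 0.0):
        self.beta = beta
        self.intercept = intercept
        self.feature_names = list(beta)

    def _margin(self, X: DesignMatrix) -> np.ndarray:
        b = np.array([self.beta[c] for c in X.columns])
        return self.intercept + X.frame.to_numpy(dtype=float) @ b

    def margin_scores(self, X: DesignMatrix) -> np.ndarray:
        return self._margin(X)

    def risk_scores(self, X: DesignMatrix) -> np.ndarray:
        return expit(self._margin(X))

    def linear_coefficients(self):
        return dict(self.beta), self.intercept


class FeatureCopyModel:
    """Risk score equals one feature's value verbatim (a 'threshold model')."""

    def __init__(self, feature: str):
        self.feature = feature

    def risk_scores(self, X: DesignMatrix) -> np.ndarray:
        return np.clip(X.frame[self.feature].to_numpy(dtype=float), 0.0, 1.0)

    def margin_scores(self, X: DesignMatrix) -> np.ndarray:
        return clamped_logit(self.risk_scores(X))


def design(df: pd.DataFrame) -> DesignMatrix:
    """Wrap an all-numeric frame as a DesignMatrix with singleton groups."""
    return DesignMatrix(df, {c: [c] for c in df.columns})


@pytest.fixture(scope="session")
def accord_cohort():
    """A mid-sized ACCORD-like cohort without missingness (session-cached)."""
    spec = accord_like_spec(n_participants=4000, seed=11, missing_rate=0.0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_linear_spec():
    """Two numeric + one binary categorical feature, known logistic truth."""
    return CohortSpec(
        n_participants=2000,
        seed=5,
        numeric_features=[("x1", 0.0, 1.0), ("x2", 0.0, 1.0)],
        categorical_features=[("g", ["a", "b"], [0.5, 0.5])],
        outcome_models={"y": (-1.0, {"x1": 1.0, "x2": -0.5, "g=b": 0.8})},
        protected=["g"],
    )
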