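"""Explanation layer: permutation importance, Shapley values, PDP."""

import numpy as np
import pandas as pd
import pytest

from conftest import FeatureCopyModel, LinearStubModel, design
from fairselect.explanation import (
    ExplainConfig,
    bootstrap_permutation_importance,
    explain_model,
    partial_dependence,
    relative_shapley,
    shapley_linear_exact,
    shapley_sampling,
)


def _stub_fit(model):
    def fit(X, y, seed):
        return model
    return fit


class TestBootstrapPermutationImportance:
    def test_constant_feature_importance_exactly_zero(self):
        rng = np.random.default_rng(0)
        X = design(pd.DataFrame({"c": np.ones(200), "x": rng.normal(size=200)}))
        y = (X.frame["x"] > 0).astype(int).to_numpy()
        cfg = ExplainConfig(n_bootstrap=5, seed=1)
        imp = bootstrap_permutation_importance(_stub_fit(FeatureCopyModel("x")), X, y, cfg)
        assert imp.table.set_index("feature").loc["c", "mean"] == 0.0

    def test_perfect_feature_drop_about_half(self):
        # risk equals a binary feature equal to the outcome: baseline AUC 1,
        # a random permutation has expected AUC 1/2, so mean drop ~= 0.5
        rng = np.random.default_rng(3)
        f = rng.integers(0, 2, 300).astype(float)
        X = design(pd.DataFrame({"f": f}))
        y = f.astype(int)
        cfg = ExplainConfig(n_bootstrap=40, permutations_per_feature=2, seed=2)
        imp = bootstrap_permutation_importance(_stub_fit(FeatureCopyModel("f")), X, y, cfg)
        mean = imp.table.set_index("feature").loc["f", "mean"]
        assert abs(mean - 0.5) < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = design(pd.DataFrame({"x": rng.normal(size=150), "z": rng.normal(size=150)}))
        y = (X.frame["x"] + rng.normal(size=150) > 0).astype(int).to_numpy()
        cfg = ExplainConfig(n_bootstrap=8, seed=42)
        a = bootstrap_permutation_importance(_stub_fit(FeatureCopyModel("x")), X, y, cfg)
        b = bootstrap_permutation_importance(_stub_fit(FeatureCopyModel("x")), X, y, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_negative_importance_preserved(self):
        # scoring against an anti-predictive feature: permuting it helps,
        # so the drop is negative and must be reported as such
        rng = np.random.default_rng(7)
        f = rng.integers(0, 2, 200).astype(float)
        X = design(pd.DataFrame({"f": f}))
        y = (1 - f).astype(int)
        cfg = ExplainConfig(n_bootstrap=10, seed=3)
        imp = bootstrap_permutation_importance(_stub_fit(FeatureCopyModel("f")), X, y, cfg)
        assert imp.table.set_index("feature").loc["f", "mean"] < 0

    def test_mostly_single_class_oob_errors(self):
        X = design(pd.DataFrame({"x": np.arange(12, dtype=float)}))
        y = np.r_[np.ones(11, int), 0]  # one negative: OOB almost always pure
        cfg = ExplainConfig(n_bootstrap=10, seed=0)
        with pytest.raises(ValueError, match="replicates usable"):
            with pytest.warns(UserWarning):
                bootstrap_permutation_importance(_stub_fit(FeatureCopyModel("x")), X, y, cfg)


class TestShapleyLinearExact:
    def test_closed_form_example(self):
        X = design(pd.DataFrame({"a": [1.0], "b": [1.0]}))
        bg = design(pd.DataFrame({"a": [0.0], "b": [0.0]}))
        shap = shapley_linear_exact({"a": 1.0, "b": -2.0}, 0.0, X, bg)
        assert shap.values.iloc[0].tolist() == [1.0, -2.0]
        assert shap.base == 0.0
        # efficiency: base + sum(phi) = margin = -1
        assert shap.base + shap.values.iloc[0].sum() == pytest.approx(-1.0)

    def test_row_at_background_mean_gets_zero(self):
        bg = design(pd.DataFrame({"a": [0.0, 2.0], "b": [1.0, 3.0]}))
        X = design(pd.DataFrame({"a": [1.0], "b": [2.0]}))  # equals bg mean
        shap = shapley_linear_exact({"a": 3.0, "b": -1.0}, 0.5, X, bg)
        np.testing.assert_allclose(shap.values.to_numpy(), 0.0, atol=1e-12)

    def test_linearity_in_beta(self):
        rng = np.random.default_rng(1)
        X = design(pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"]))
        bg = design(pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"]))
        s1 = shapley_linear_exact({"a": 1.0, "b": 0.5}, 0.0, X, bg)
        s2 = shapley_linear_exact({"a": 2.0, "b": 1.0}, 0.0, X, bg)
        np.testing.assert_allclose(2 * s1.values.to_numpy(), s2.values.to_numpy())

    def test_empty_background_rejected(self):
        X = design(pd.DataFrame({"a": [1.0]}))
        bg = design(pd.DataFrame({"a": []}))
        with pytest.raises(ValueError, match="background"):
            shapley_linear_exact({"a": 1.0}, 0.0, X, bg)


class TestShapleySampling:
    def _linear_setup(self, n=6, d=3, seed=0):
        rng = np.random.default_rng(seed)
        cols = [f"f{i}" for i in range(d)]
        X = design(pd.DataFrame(rng.normal(size=(n, d)), columns=cols))
        bg = design(pd.DataFrame(rng.normal(size=(10, d)), columns=cols))
        beta = {c: float(b) for c, b in zip(cols, rng.normal(size=d))}
        return X, bg, LinearStubModel(beta, intercept=0.3)

    def test_agrees_with_exact_linear_within_3se(self):
        X, bg, model = self._linear_setup()
        cfg = ExplainConfig(shapley_samples=200, seed=9)
        approx = shapley_sampling(model, X, bg, cfg)
        exact = shapley_linear_exact(model.beta, model.intercept, X, bg)
        diff = (approx.values - exact.values).abs().to_numpy()
        bound = 3 * approx.se.to_numpy() + 1e-9
        assert (diff <= bound).mean() > 0.95

    def test_two_feature_exhaustive_enumeration_exact(self):
        rng = np.random.default_rng(2)
        cols = ["a", "b"]
        X = design(pd.DataFrame(rng.normal(size=(4, 2)), columns=cols))
        bg = design(pd.DataFrame(rng.normal(size=(3, 2)), columns=cols))
        model = LinearStubModel({"a": 1.2, "b": -0.7}, 0.1)
        # budget covers all 2! x 3 (ordering, background) pairs -> exact
        cfg = ExplainConfig(shapley_samples=6, seed=0)
        approx = shapley_sampling(model, X, bg, cfg)
        exact = shapley_linear_exact(model.beta, model.intercept, X, bg)
        np.testing.assert_allclose(approx.values.to_numpy(), exact.values.to_numpy(), atol=1e-9)
        assert np.all(approx.se.to_numpy() == 0.0)

    def test_efficiency_exact_per_row(self):
        X, bg, model = self._linear_setup(seed=4)
        cfg = ExplainConfig(shapley_samples=25, seed=1)
        shap = shapley_sampling(model, X, bg, cfg)
        lhs = shap.values.sum(axis=1) + shap.base
        np.testing.assert_allclose(lhs.to_numpy(), model.margin_scores(X), atol=1e-9)

    def test_deterministic_given_seed(self):
        X, bg, model = self._linear_setup(seed=5)
        cfg = ExplainConfig(shapley_samples=30, seed=3)
        a = shapley_sampling(model, X, bg, cfg)
        b = shapley_sampling(model, X, bg, cfg)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestRelativeShapley:
    def _shap(self, rows):
        vals = pd.DataFrame(rows, columns=[f"f{i}" for i in range(len(rows[0]))])
        from fairselect.explanation import ShapMatrix

        return ShapMatrix(vals, base=0.0)

    def test_single_feature_is_one(self):
        rel = relative_shapley(self._shap([[0.5], [-2.0]]))
        np.testing.assert_allclose(rel.values.to_numpy().ravel(), [1.0, 1.0])

    def test_arithmetic(self):
        rel = relative_shapley(self._shap([[0.3, 0.1]]))
        np.testing.assert_allclose(rel.values.iloc[0].to_numpy(), [0.75, 0.25])

    def test_sign_preserved(self):
        rel = relative_shapley(self._shap([[-0.1, 0.5]]))
        assert rel.values.iloc[0, 0] < 0 < rel.values.iloc[0, 1]

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        rel = relative_shapley(self._shap(rng.normal(size=(20, 4)).tolist()))
        sums = rel.values.loc[rel.valid].sum(axis=1)
        np.testing.assert_allclose(sums.to_numpy(), 1.0)

    def test_degenerate_rows_flagged_and_all_degenerate_errors(self):
        rel = relative_shapley(self._shap([[0.2, -0.2], [0.3, 0.1]]))
        assert rel.valid.tolist() == [False, True]
        with pytest.raises(ValueError, match="zero total"):
            relative_shapley(self._shap([[0.2, -0.2]]))


class TestPartialDependence:
    def test_ignored_feature_flat_curve(self):
        rng = np.random.default_rng(0)
        X = design(pd.DataFrame({"used": rng.normal(size=50), "ignored": rng.normal(size=50)}))
        model = LinearStubModel({"used": 1.0, "ignored": 0.0}, 0.0)
        curve = partial_dependence(model, X, "ignored", ExplainConfig(pdp_grid_size=10))
        assert np.ptp(curve.mean_margin) < 1e-12
        assert curve.mean_margin[0] == pytest.approx(model.margin_scores(X).mean())

    def test_log_odds_slope_recovers_coefficient(self):
        rng = np.random.default_rng(1)
        X = design(pd.DataFrame({"a": rng.normal(size=80), "b": rng.normal(size=80)}))
        beta_a = 0.73
        model = LinearStubModel({"a": beta_a, "b": -0.4}, 0.2)
        curve = partial_dependence(model, X, "a", ExplainConfig(pdp_grid_size=20))
        slopes = np.diff(curve.mean_margin) / np.diff(curve.grid)
        np.testing.assert_allclose(slopes, beta_a, atol=1e-9)

    def test_binary_indicator_two_grid_points(self):
        rng = np.random.default_rng(2)
        X = design(pd.DataFrame({"ind": rng.integers(0, 2, 40).astype(float)}))
        model = LinearStubModel({"ind": 1.0}, 0.0)
        curve = partial_dependence(model, X, "ind")
        assert len(curve.grid) == 2

    def test_risk_curve_in_unit_interval(self):
        rng = np.random.default_rng(3)
        X = design(pd.DataFrame({"a": rng.normal(size=30)}))
        curve = partial_dependence(LinearStubModel({"a": 2.0}, 0.0), X, "a")
        assert np.all((curve.mean_risk >= 0) & (curve.mean_risk <= 1))

    def test_unknown_feature_rejected(self):
        X = design(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="unknown feature"):
            partial_dependence(LinearStubModel({"a": 1.0}, 0.0), X, "zzz")


class TestExplainModel:
    def test_dominant_feature_leads_all_three_views(self):
        # one overwhelming coefficient: it must rank 1 in importance, have
        # the largest mean |relative Shapley|, and the steepest PDP slope
        from fairselect.models import ModelSpec, tune_and_fit

        rng = np.random.default_rng(8)
        n = 600
        X = design(
            pd.DataFrame(
                {"big": rng.normal(size=n), "small": rng.normal(size=n), "null": rng.normal(size=n)}
            )
        )
        lp = 2.0 * X.frame["big"].to_numpy() + 0.2 * X.frame["small"].to_numpy()
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-lp))).astype(int)
        model = tune_and_fit(ModelSpec("penalized-logistic", {"C": [10.0]}, None, 0), X, y)
        cfg = ExplainConfig(n_bootstrap=15, shapley_samples=20, top_k=3, seed=4)
        imp, shap, rel, curves = explain_model(model, X, y, cfg)
        assert imp.top_features(1) == ["big"]
        assert rel.summary.abs().idxmax() == "big"
        slopes = {
            f: abs(np.diff(c.mean_margin) / np.diff(c.grid)).mean() for f, c in curves.items()
        }
        assert max(slopes, key=slopes.get) == "big"

    def test_top_k_clamped_to_feature_count(self):
        rng = np.random.default_rng(9)
        X = design(pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)}))
        y = (rng.uniform(size=300) < 1 / (1 + np.exp(-X.frame["a"].to_numpy()))).astype(int)
        from fairselect.models import ModelSpec, tune_and_fit

        model = tune_and_fit(ModelSpec("penalized-logistic", {"C": [1.0]}, None, 0), X, y)
        cfg = ExplainConfig(n_bootstrap=5, shapley_samples=8, top_k=10, seed=0)
        _, _, _, curves = explain_model(model, X, y, cfg)
        assert set(curves) == {"a", "b"}
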