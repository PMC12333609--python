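"""Penalized-spline binomial GAM: bases, fitting, prediction, importance."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from coastsdm.design import SdmDesign
from coastsdm.gam import (
    build_smooth,
    deviance_importance,
    fit_gam,
    partial_response,
    predict_gam,
)
from coastsdm.grid import InvalidInputError, PredictorStack

from conftest import make_grid

COARSE = np.logspace(-3, 3, 7)


def design_from(x_dict, y, weight=None):
    df = pd.DataFrame(x_dict)
    df["label"] = y
    if weight is not None:
        df["weight"] = weight
    return SdmDesign(df)


def logistic_design(rng, n, beta, intercept=0.0):
    x = rng.normal(size=n)
    y = rng.random(n) < expit(intercept + beta * x)
    return design_from({"x": x}, y.astype(int)), x, y


class TestBuildSmooth:
    def test_partition_of_unity_before_centering(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200)
        for k in (3, 5, 10):
            spec = build_smooth(vals, k)
            B, _ = spec.basis(vals)
            assert B.shape[1] == k
            assert np.allclose(B.sum(axis=1), 1.0)

    def test_penalty_annihilates_linear_coefficient_sequences(self):
        spec = build_smooth(np.linspace(0, 1, 50), 8)
        for coefs in (np.ones(8), np.arange(8.0), 3.0 - 0.5 * np.arange(8)):
            assert coefs @ spec.penalty @ coefs == pytest.approx(0.0, abs=1e-10)
        wiggly = np.array([0, 1, 0, 1, 0, 1, 0, 1.0])
        assert wiggly @ spec.penalty @ wiggly > 1.0

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(InvalidInputError):
            build_smooth(np.array([1.0, 1.0, 2.0, 2.0]), 5)
        with pytest.raises(InvalidInputError):
            build_smooth(np.linspace(0, 1, 10), 2)


class TestFitGam:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        design = design_from({}, y)
        fit = fit_gam(design, [])
        assert expit(fit.intercept) == pytest.approx(0.30, abs=1e-8)
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-10)

    def test_permuted_labels_give_null_fit(self):
        rng = np.random.default_rng(1)
        design, x, _ = logistic_design(rng, 500, beta=2.0)
        permuted = design.table.copy()
        permuted["label"] = rng.permutation(permuted["label"].to_numpy())
        design0 = SdmDesign(permuted)
        spec = build_smooth(x, 5, "x")
        fit = fit_gam(design0, [spec], lambda_grid=COARSE)
        assert fit.deviance_explained < 0.05
        assert np.abs(fit.beta[1:]).max() < 0.5

    def test_linear_logit_recovered_against_glm_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        design, x, y = logistic_design(rng, 500, beta=1.5, intercept=0.3)
        spec = build_smooth(x, 5, "x")
        fit = fit_gam(design, [spec])
        oracle = sm.GLM(y.astype(float), sm.add_constant(x),
                        family=sm.families.Binomial()).fit()
        # compare fitted logit curves over the central 90% of x
        grid = np.linspace(np.quantile(x, 0.05), np.quantile(x, 0.95), 50)
        curve = partial_response(fit, "x", 50)
        B, _ = spec.centered_basis(grid)
        eta_fit = fit.intercept + B @ fit.beta[1:]
        eta_true = oracle.params[0] + oracle.params[1] * grid
        assert np.abs(eta_fit - eta_true).max() < 0.35
        # slope of the fitted smooth within 10% of the GLM slope
        slope_fit = np.polyfit(grid, eta_fit, 1)[0]
        assert slope_fit == pytest.approx(oracle.params[1], rel=0.10)

    def test_infinite_penalty_collapses_to_intercept_only(self):
        rng = np.random.default_rng(3)
        design, x, _ = logistic_design(rng, 200, beta=1.0)
        spec = build_smooth(x, 5, "x")
        shrunk = fit_gam(design, [spec], fixed_lambda=1e12, fixed_epsilon=1e12)
        null = fit_gam(design, [])
        assert shrunk.residual_deviance == pytest.approx(null.residual_deviance, abs=1e-6)

    def test_unpenalized_limit_beats_glm_on_same_basis(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        design, x, y = logistic_design(rng, 200, beta=1.0)
        spec = build_smooth(x, 8, "x")
        fit = fit_gam(design, [spec], fixed_lambda=1e-10, fixed_epsilon=1e-10)
        B, _ = spec.centered_basis(x)
        X = np.column_stack([np.ones(len(x)), B])
        glm = sm.GLM(y.astype(float), X, family=sm.families.Binomial()).fit()
        assert fit.residual_deviance <= glm.deviance + 1e-4

    def test_aic_decreases_when_true_term_added(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            design, x, _ = logistic_design(rng, 500, beta=1.0)
            spec = build_smooth(x, 5, "x")
            with_term = fit_gam(design, [spec], lambda_grid=COARSE)
            without = fit_gam(design, [])
            wins += with_term.aic < without.aic
        assert wins >= 9

    def test_predictor_rescaling_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(5)
        design, x, _ = logistic_design(rng, 300, beta=1.0)
        spec = build_smooth(x, 5, "x")
        fit = fit_gam(design, [spec], fixed_lambda=1.0, fixed_epsilon=0.01)
        scaled = design.table.copy()
        scaled["x"] = 10.0 * scaled["x"] - 3.0
        design2 = SdmDesign(scaled)
        spec2 = build_smooth(scaled["x"].to_numpy(), 5, "x")
        fit2 = fit_gam(design2, [spec2], fixed_lambda=1.0, fixed_epsilon=0.01)
        p1 = fit.predict_table(design.table)
        p2 = fit2.predict_table(design2.table)
        assert np.abs(p1 - p2).max() < 1e-8

    def test_both_classes_required(self):
        with pytest.raises(InvalidInputError):
            fit_gam(design_from({}, np.ones(10, dtype=int)), [])


class TestPredictGam:
    def grid_stack(self, fn, n=12):
        g = make_grid(np.zeros((n, n)), cell=100.0)
        xs, _ = g.cell_centers()
        vals = fn(xs / xs.max())
        return PredictorStack({"x": g.with_values(vals)})

    def test_intercept_only_constant_probability_and_se(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_gam(design_from({}, y), [])
        stack = self.grid_stack(lambda u: u)
        prob, se = predict_gam(fit, stack)
        assert np.allclose(prob.values, 0.30, atol=1e-8)
        assert np.allclose(se.values, se.values[0, 0])
        assert (se.values > 0).all()

    def test_monotone_smooth_gives_monotone_probability(self):
        rng = np.random.default_rng(6)
        design, x, _ = logistic_design(rng, 800, beta=2.0)
        spec = build_smooth(x, 5, "x")
        fit = fit_gam(design, [spec])
        stack = self.grid_stack(lambda u: np.quantile(x, 0.05)
                                + u * (np.quantile(x, 0.95) - np.quantile(x, 0.05)))
        prob, se = predict_gam(fit, stack)
        row = prob.values[0, :]
        assert row[-1] > row[0] + 0.2
        assert np.all(np.diff(row) > -1e-6)
        assert (se.values > 0).all()

    def test_out_of_range_cells_flagged(self):
        rng = np.random.default_rng(7)
        design, x, _ = logistic_design(rng, 300, beta=1.0)
        spec = build_smooth(x, 5, "x")
        fit = fit_gam(design, [spec])
        stack = self.grid_stack(lambda u: x.min() + u * 3 * (x.max() - x.min()))
        prob, se, cover = predict_gam(fit, stack, return_coverage=True)
        assert cover.values.max() == 1.0
        assert np.isfinite(prob.values).all()


class TestImportanceAndPartials:
    def test_single_predictor_owns_all_explained_deviance(self):
        rng = np.random.default_rng(8)
        design, x, _ = logistic_design(rng, 400, beta=1.5)
        table = deviance_importance(design, [build_smooth(x, 5, "x")],
                                    lambda_grid=COARSE)
        assert table.loc[0, "proportion_of_total"] == pytest.approx(1.0, abs=1e-8)

    def test_noise_predictor_contributes_little(self):
        rng = np.random.default_rng(9)
        n = 600
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = (rng.random(n) < expit(2.0 * x)).astype(int)
        design = design_from({"x": x, "noise": noise}, y)
        specs = [build_smooth(x, 5, "x"), build_smooth(noise, 5, "noise")]
        table = deviance_importance(design, specs, lambda_grid=COARSE).set_index("predictor")
        assert table.loc["noise", "proportion_of_total"] < 0.05
        assert table.loc["x", "proportion_of_total"] > 0.5

    def test_partial_response_centering_and_linearity(self):
        rng = np.random.default_rng(10)
        design, x, _ = logistic_design(rng, 800, beta=1.5)
        spec = build_smooth(x, 5, "x")
        fit = fit_gam(design, [spec])
        # centering: the fitted smooth averages to zero over the training rows
        B, _ = spec.centered_basis(x)
        assert abs((B @ fit.beta[1:]).mean()) < 1e-8
        curve = partial_response(fit, "x", 80)
        lo, hi = np.quantile(x, [0.05, 0.95])
        central = (curve["x"] >= lo) & (curve["x"] <= hi)
        coef = np.polyfit(curve.loc[central, "x"], curve.loc[central, "effect"], 1)
        resid = curve.loc[central, "effect"] - np.polyval(coef, curve.loc[central, "x"])
        assert np.abs(resid).max() < 0.1

    def test_uninformative_term_shrinks_flat(self):
        rng = np.random.default_rng(11)
        n = 500
        x = rng.normal(size=n)
        y = rng.integers(0, 2, size=n)
        design = design_from({"x": x}, y)
        fit = fit_gam(design, [build_smooth(x, 5, "x")])
        curve = partial_response(fit, "x", 50)
        assert (np.abs(curve["effect"]) <= 2 * curve["se"] + 1e-6).all()

    def test_unknown_predictor_rejected(self):
        fit = fit_gam(design_from({}, np.array([0, 1] * 5)), [])
        with pytest.raises(InvalidInputError):
            partial_response(fit, "ghost")
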