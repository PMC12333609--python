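"""Maximum-entropy engine: features, optimizer, outputs, importance."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from coastsdm.design import SdmDesign
from coastsdm.grid import InvalidInputError, PredictorStack
from coastsdm.maxent import (
    FeatureDef,
    FeatureSet,
    bootstrap_predict,
    fit_maxent,
    make_features,
    percent_contribution,
    permutation_importance,
    predict_maxent,
)

from conftest import make_grid


def design(values_dict, label=1):
    df = pd.DataFrame(values_dict)
    df["label"] = label
    return SdmDesign(df)


def binary_problem(p=0.8, q=0.2, m=200, n=1000):
    """Presences with feature frequency p, background with frequency q."""
    pres = design({"f": np.r_[np.ones(int(m * p)), np.zeros(m - int(m * p))]})
    bg = design({"f": np.r_[np.ones(int(n * q)), np.zeros(n - int(n * q))]}, label=0)
    feats = FeatureSet([FeatureDef("f", "linear", 0.0, 1.0)])
    return pres, bg, feats


class TestMakeFeatures:
    def test_scaling_endpoints_and_hinge_definition(self):
        rng = np.random.default_rng(0)
        bg = design({"x": rng.uniform(2.0, 10.0, 500)}, label=0)
        feats = make_features(bg, bg, n_hinge_knots=3)
        lin = next(f for f in feats.features if f.kind == "linear")
        assert lin.transform(np.array([bg.table["x"].max()]))[0] == pytest.approx(1.0)
        assert lin.transform(np.array([bg.table["x"].min()]))[0] == pytest.approx(0.0)
        fwd = next(f for f in feats.features if f.kind == "hinge_forward")
        assert fwd.transform(np.array([fwd.knot - 1.0]))[0] == 0.0
        assert fwd.transform(np.array([feats.features[0].hi]))[0] == pytest.approx(1.0)

    def test_feature_count_small_support(self):
        bg = design({"x": np.array([0.0, 1.0, 2.0, 3.0] * 10)}, label=0)
        feats = make_features(bg, bg, n_hinge_knots=2)
        kinds = [f.kind for f in feats.features]
        assert kinds.count("linear") == 1
        assert kinds.count("quadratic") == 1
        assert kinds.count("hinge_forward") == 2
        assert kinds.count("hinge_reverse") == 2

    def test_constant_predictor_dropped(self):
        bg = design({"x": np.ones(50), "y": np.arange(50.0)}, label=0)
        feats = make_features(bg, bg, n_hinge_knots=2)
        assert all(f.parent == "y" for f in feats.features)

    def test_all_features_map_to_unit_interval(self):
        rng = np.random.default_rng(1)
        bg = design({"x": rng.normal(size=400), "z": rng.exponential(size=400)}, label=0)
        feats = make_features(bg, bg, n_hinge_knots=10)
        F = feats.matrix(bg.table)
        assert F.min() >= 0.0 and F.max() <= 1.0 + 1e-12


class TestFitMaxent:
    def test_single_binary_feature_closed_form(self):
        pres, bg, feats = binary_problem()
        fit = fit_maxent(pres, bg, feats, beta=0.0)
        assert fit.lambdas[0] == pytest.approx(np.log(16.0), abs=1e-3)

    def test_matches_brute_force_on_two_features(self):
        rng = np.random.default_rng(2)
        pres = design({"a": rng.random(15), "b": rng.random(15)})
        bg = design({"a": rng.random(20), "b": rng.random(20)}, label=0)
        feats = FeatureSet([FeatureDef("a", "linear", 0.0, 1.0),
                            FeatureDef("b", "linear", 0.0, 1.0)])
        beta = 0.1
        fit = fit_maxent(pres, bg, feats, beta=beta, iterations=5000, tol=1e-12)

        Fp, Fb = feats.matrix(pres.table), feats.matrix(bg.table)
        pbar = Fp.mean(axis=0)
        beta_j = fit.reg_amounts

        def neg_gain(lam):
            eta = Fb @ lam
            return -(pbar @ lam - np.log(np.exp(eta).sum()) + np.log(len(Fb))
                     - beta_j @ np.abs(lam))

        best = min(
            (minimize(neg_gain, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
             for x0 in (np.zeros(2), np.ones(2), -np.ones(2))),
            key=lambda r: r.fun,
        )
        assert np.abs(fit.lambdas - best.x).max() < 1e-3

    def test_null_presences_give_null_model(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        bg = design({"x": x}, label=0)
        pres = design({"x": rng.choice(x, size=200, replace=False)})
        feats = FeatureSet([FeatureDef("x", "linear", x.min(), x.max()),
                            FeatureDef("x", "quadratic", (x**2).min(), (x**2).max())])
        fit = fit_maxent(pres, bg, feats, beta=1.0)
        assert np.abs(fit.lambdas).max() < 0.05
        assert fit.regularized_gain < 0.01

    def test_huge_beta_kills_every_feature(self):
        pres, bg, feats = binary_problem()
        fit = fit_maxent(pres, bg, feats, beta=100.0)
        assert np.all(fit.lambdas == 0.0)
        assert fit.regularized_gain == pytest.approx(0.0, abs=1e-12)

    def test_moment_matching_at_zero_beta(self):
        rng = np.random.default_rng(4)
        pres = design({"a": rng.random(80), "b": rng.random(80)})
        bg = design({"a": rng.random(400), "b": rng.random(400)}, label=0)
        feats = make_features(pres, bg, n_hinge_knots=2)
        assert len(feats) <= 12
        fit = fit_maxent(pres, bg, feats, beta=0.0, iterations=20000, tol=1e-14)
        Fb = feats.matrix(bg.table)
        w = np.exp(Fb @ fit.lambdas - fit.log_partition)
        fitted_means = w @ Fb
        pbar = feats.matrix(pres.table).mean(axis=0)
        assert np.abs(fitted_means - pbar).max() < 1e-4

    def test_gain_is_monotone_over_cycles(self):
        rng = np.random.default_rng(5)
        pres = design({"x": rng.normal(1.0, 1.0, 60)})
        bg = design({"x": rng.normal(0.0, 1.5, 800)}, label=0)
        feats = make_features(pres, bg, n_hinge_knots=10)
        fit = fit_maxent(pres, bg, feats, beta=1.0)
        gains = np.array(fit.cycle_gains)
        assert (np.diff(gains) >= -1e-9).all()

    def test_l1_norm_shrinks_as_beta_grows(self):
        rng = np.random.default_rng(6)
        pres = design({"x": rng.normal(1.0, 0.7, 60)})
        bg = design({"x": rng.normal(0.0, 1.5, 600)}, label=0)
        feats = make_features(pres, bg, n_hinge_knots=5)
        norms = [np.abs(fit_maxent(pres, bg, feats, beta=b).lambdas).sum()
                 for b in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_input_validation(self):
        pres, bg, feats = binary_problem()
        with pytest.raises(InvalidInputError):
            fit_maxent(pres, bg, feats, beta=-1.0)
        empty = SdmDesign(pd.DataFrame({"f": [], "label": []}))
        with pytest.raises(InvalidInputError):
            fit_maxent(empty, bg, feats)


class TestPredictMaxent:
    def stack_from(self, values):
        return PredictorStack({"f": make_grid(values, cell=100.0)})

    def test_null_model_uniform_raw_and_half_logistic(self):
        pres, bg, feats = binary_problem()
        fit = fit_maxent(pres, bg, feats, beta=1e6)  # all lambdas zero
        stack = self.stack_from(np.random.default_rng(7).random((5, 5)))
        raw, logistic = predict_maxent(fit, stack)
        assert np.allclose(raw.values, 1.0 / fit.n_background)
        assert np.allclose(logistic.values, 0.5)

    def test_logistic_orders_like_raw_and_binary_contrast(self):
        pres, bg, feats = binary_problem()
        fit = fit_maxent(pres, bg, feats, beta=0.0)
        vals = np.zeros((2, 3))
        vals[1, :] = 1.0
        raw, logistic = predict_maxent(fit, self.stack_from(vals))
        assert (logistic.values[1, :] > logistic.values[0, :]).all()
        order = np.argsort(raw.values.ravel())
        assert np.array_equal(order, np.argsort(logistic.values.ravel()))


class TestImportance:
    def informative_pair(self, seed=8, duplicate=False):
        rng = np.random.default_rng(seed)
        n, m = 1000, 100
        xb = rng.normal(size=n)
        zb = xb.copy() if duplicate else rng.normal(size=n)
        keep = rng.random(m * 10) < 0.5
        xp = rng.normal(1.2, 0.8, size=m)
        zp = xp.copy() if duplicate else rng.normal(size=m)
        pres = design({"x": xp, "z": zp})
        bg = design({"x": xb, "z": zb}, label=0)
        feats = make_features(pres, bg, n_hinge_knots=5)
        return pres, bg, feats

    def test_single_predictor_gets_full_credit(self):
        rng = np.random.default_rng(9)
        pres = design({"x": rng.normal(1.0, 0.8, 80)})
        bg = design({"x": rng.normal(size=900)}, label=0)
        feats = make_features(pres, bg, n_hinge_knots=5)
        fit = fit_maxent(pres, bg, feats, beta=1.0)
        contrib = percent_contribution(fit)
        assert contrib.loc[0, "percent_contribution"] == pytest.approx(100.0)
        perm = permutation_importance(fit, pres, bg, seed=1)
        assert perm.loc[0, "permutation_importance"] == pytest.approx(100.0)

    def test_uninformative_predictor_gets_no_permutation_credit(self):
        pres, bg, feats = self.informative_pair()
        fit = fit_maxent(pres, bg, feats, beta=1.0)
        perm = permutation_importance(fit, pres, bg, seed=2).set_index("predictor")
        assert perm.loc["x", "permutation_importance"] > perm.loc["z", "permutation_importance"]
        contrib = percent_contribution(fit)
        assert contrib["percent_contribution"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_duplicated_informative_predictors_share_importance(self):
        pres, bg, feats = self.informative_pair(duplicate=True)
        fit = fit_maxent(pres, bg, feats, beta=1.0)
        perm = permutation_importance(fit, pres, bg, seed=3)
        vals = perm.set_index("predictor")["permutation_importance"]
        assert vals.max() < 100.0
        assert vals.sum() == pytest.approx(100.0, abs=1e-6)


class TestBootstrap:
    def test_determinism_range_and_spread(self):
        rng = np.random.default_rng(10)
        pres = design({"f": rng.normal(1.0, 0.5, 40)})
        bg = design({"f": rng.normal(0.0, 1.0, 400)}, label=0)
        feats = make_features(pres, bg, n_hinge_knots=3)
        stack = PredictorStack({"f": make_grid(rng.normal(size=(6, 6)), cell=100.0)})
        reps1 = bootstrap_predict(pres, bg, feats, stack, n_replicates=3, beta=1.0, seed=5)
        reps2 = bootstrap_predict(pres, bg, feats, stack, n_replicates=3, beta=1.0, seed=5)
        for a, b in zip(reps1, reps2):
            assert np.array_equal(a.values, b.values, equal_nan=True)
        stackvals = np.stack([r.values for r in reps1])
        assert (stackvals > 0).all() and (stackvals < 1).all()
        # replicates differ (resampling is real)
        assert not np.array_equal(reps1[0].values, reps1[1].values)
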