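"""The five mapping estimators, design construction, prediction, registry."""

import dataclasses
import json
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import factbmap as fm
from factbmap.errors import (
    CollinearityError,
    DegenerateLikelihoodError,
    RegistryLookupError,
    SchemaError,
    TransformDomainError,
    UndefinedPredictionError,
)
from factbmap.estimators import (
    fit_clad,
    fit_logistic_quantile,
    fit_ols,
    fit_quantile,
    fit_tobit,
    model_spec,
)


def toy_cohort(rows):
    return fm.Cohort(pd.DataFrame(rows))


class TestBuildDesign:
    def test_column_layout_and_order(self):
        rows = [dict(PWB=20, SWB=21, EWB=15, FWB=18, BCS=25, utility=0.8) for _ in range(3)]
        X, y = fm.build_design(toy_cohort(rows), model_spec(4))
        assert X.shape == (3, 5)  # intercept + 4 covariates
        assert np.all(X[:, 0] == 1)
        X1, _ = fm.build_design(toy_cohort(rows), model_spec(1))
        assert X1.shape[1] == 6

    def test_rows_with_undefined_covariate_dropped(self):
        rows = [
            dict(PWB=20, SWB=21, EWB=15, FWB=18, BCS=25, utility=0.8),
            dict(PWB=20, SWB=np.nan, EWB=15, FWB=18, BCS=25, utility=0.7),
        ]
        X, _ = fm.build_design(toy_cohort(rows), model_spec(1))
        assert X.shape[0] == 1
        # SWB not in Model 4, so the same row survives there
        X4, _ = fm.build_design(toy_cohort(rows), model_spec(4))
        assert X4.shape[0] == 2

    def test_empty_design_raises(self):
        rows = [dict(PWB=np.nan, SWB=1, EWB=1, FWB=1, BCS=1, utility=0.5)]
        with pytest.raises(fm.FactbmapError):
            fm.build_design(toy_cohort(rows), model_spec(4))


class TestOls:
    def test_exact_linear_interpolation(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([np.ones(10), x])
        y = 0.3 + 0.01 * x
        m = fit_ols(X, y)
        assert m.intercept == pytest.approx(0.3, abs=1e-10)
        assert m.coefficients["x1"] == pytest.approx(0.01, abs=1e-10)

    def test_residuals_sum_to_zero_and_mean_preserved(self, baseline_cohort):
        m = fm.fit("ols", baseline_cohort, 4)
        pred = fm.predict(m, baseline_cohort.data)
        assert np.mean(pred) == pytest.approx(np.mean(baseline_cohort.utility), abs=1e-10)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(123)
        n = 1000
        x = rng.normal(20, 6, n)
        X = np.column_stack([np.ones(n), x])
        y = 0.3 + 0.01 * x + rng.normal(0, 0.08, n)
        m = fit_ols(X, y)
        assert abs(m.intercept - 0.3) < 3 * m.standard_errors["const"]
        assert abs(m.coefficients["x1"] - 0.01) < 3 * m.standard_errors["x1"]

    def test_duplicated_column_raises(self):
        x = np.arange(6, dtype=float)
        X = np.column_stack([np.ones(6), x, x])
        with pytest.raises(CollinearityError):
            fit_ols(X, x)


class TestTobit:
    def test_equals_ols_without_censoring(self, baseline_cohort):
        X, y = fm.build_design(baseline_cohort, model_spec(4), outcome="latent_utility")
        ols = fit_ols(X, y)
        tob = fit_tobit(X, y, censor_point=float(y.max()) + 1.0)
        for t in ols.spec.terms:
            assert tob.coefficients[t] == pytest.approx(ols.coefficients[t], abs=1e-4)
        assert tob.intercept == pytest.approx(ols.intercept, abs=1e-4)

    def test_censored_recovery_and_smaller_bias_than_ols(
        self, heavy_ceiling_cohort, heavy_ceiling_truth
    ):
        tob = fm.fit("tobit", heavy_ceiling_cohort, 4)
        ols = fm.fit("ols", heavy_ceiling_cohort, 4)
        truth = heavy_ceiling_truth
        assert (heavy_ceiling_cohort.utility == 1).mean() > 0.15
        tobit_bias = ols_bias = 0.0
        for t in truth.spec.terms:
            b_t = abs(tob.coefficients[t] - truth.coefficients[t])
            assert b_t < 3 * tob.standard_errors[t]
            tobit_bias += b_t
            ols_bias += abs(ols.coefficients[t] - truth.coefficients[t])
        assert tobit_bias < ols_bias
        assert tob.sigma > 0

    def test_all_censored_degenerate(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(DegenerateLikelihoodError):
            fit_tobit(X, np.ones(5), censor_point=1.0)


class TestQuantile:
    def test_matches_brute_force_subset_oracle(self):
        # at an LAD optimum some p+1 residuals are zero: enumerate exact fits
        rng = np.random.default_rng(42)
        for trial in range(4):
            n, p = 8, 2
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
            y = rng.normal(size=n)
            m = fit_quantile(X, y)
            best = np.inf
            for idx in combinations(range(n), p + 1):
                Xi = X[list(idx)]
                if np.linalg.matrix_rank(Xi) < p + 1:
                    continue
                beta = np.linalg.solve(Xi, y[list(idx)])
                best = min(best, 0.5 * np.abs(y - X @ beta).sum())
            assert m.diagnostics["objective"] == pytest.approx(best, abs=1e-9)

    def test_noiseless_line_matches_ols(self):
        x = np.linspace(0, 10, 9)
        X = np.column_stack([np.ones(9), x])
        y = 1.0 + 0.5 * x
        q = fit_quantile(X, y)
        o = fit_ols(X, y)
        assert q.intercept == pytest.approx(o.intercept, abs=1e-8)
        assert q.coefficients["x1"] == pytest.approx(o.coefficients["x1"], abs=1e-8)

    def test_lad_objective_beats_ols_absolute_loss(self, baseline_cohort):
        X, y = fm.build_design(baseline_cohort, model_spec(4))
        q = fit_quantile(X, y)
        o = fit_ols(X, y)
        ols_beta = np.array([o.intercept] + [o.coefficients[t] for t in o.spec.terms])
        ols_abs = 0.5 * np.abs(y - X @ ols_beta).sum()
        assert q.diagnostics["objective"] <= ols_abs + 1e-9

    def test_invariance_under_outcome_rescaling(self, baseline_cohort):
        X, y = fm.build_design(baseline_cohort, model_spec(5))
        m1 = fit_quantile(X, y)
        m2 = fit_quantile(X, 10.0 * y)
        assert m2.intercept == pytest.approx(10 * m1.intercept, abs=1e-6)
        for t in m1.spec.terms:
            assert m2.coefficients[t] == pytest.approx(10 * m1.coefficients[t], abs=1e-6)

    def test_tau_domain(self):
        X = np.ones((5, 1))
        with pytest.raises(SchemaError):
            fit_quantile(X, np.arange(5.0), tau=1.5)


class TestClad:
    def test_equals_median_regression_when_no_trimming(self, baseline_cohort):
        # keep fitted values below the ceiling by fitting on the latent scale
        X, y = fm.build_design(baseline_cohort, model_spec(4), outcome="latent_utility")
        lad = fit_quantile(X, y)
        clad = fit_clad(X, y, censor_point=float((X @ _beta(lad)).max()) + 0.1)
        for t in lad.spec.terms:
            assert clad.coefficients[t] == pytest.approx(lad.coefficients[t], abs=1e-10)
        assert clad.diagnostics["n_trimmed"] == 0
        assert clad.diagnostics["iterations"] == 1

    def test_kept_set_monotone_and_converges(self, heavy_ceiling_cohort):
        m = fm.fit("clad", heavy_ceiling_cohort, 4)
        hist = m.diagnostics["kept_history"]
        assert all(a >= b for a, b in zip(hist, hist[1:]))
        assert m.diagnostics["n_trimmed"] > 0

    def test_degenerate_when_everything_fitted_above_ceiling(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = np.full(6, 5.0)  # constant high outcome, censor point far below fit
        with pytest.raises((DegenerateLikelihoodError, fm.FactbmapError)):
            fit_clad(X, y, censor_point=-1.0)

    def test_censored_recovery_within_bootstrap_se(
        self, heavy_ceiling_cohort, heavy_ceiling_truth
    ):
        spec = model_spec(4)
        X, y = fm.build_design(heavy_ceiling_cohort, spec)
        se = fm.bootstrap_se(lambda Xb, yb: fit_clad(Xb, yb, spec=spec), X, y, n_boot=60, seed=2)
        m = fit_clad(X, y, spec=spec)
        truth = heavy_ceiling_truth
        for t in truth.spec.terms:
            assert abs(m.coefficients[t] - truth.coefficients[t]) < 3 * se[t]


def _beta(m):
    return np.array([m.intercept] + [m.coefficients[t] for t in m.spec.terms])


class TestLogisticQuantile:
    def test_training_predictions_strictly_inside_bounds(self, baseline_cohort):
        b = fm.derive_bounds(float(baseline_cohort.utility.min()), 0.01)
        m = fm.fit("lqr", baseline_cohort, 4, bounds=b)
        pred = fm.predict(m, baseline_cohort.data)
        assert np.all(pred > b.y_min) and np.all(pred < b.y_max)
        assert np.mean(np.abs(pred - 1.0) <= 1e-12) == 0.0  # 0% at the ceiling

    def test_recovery_under_own_generator(self):
        rng = np.random.default_rng(3)
        n = 2000
        b = fm.bounds_preset("japanese")
        x = rng.uniform(0, 40, n)
        h = 0.5 + 0.02 * x + rng.laplace(0, 0.3, n)
        y = fm.inverse_logit_transform(h, b)
        X = np.column_stack([np.ones(n), x])
        m = fit_logistic_quantile(X, y, b)
        se = fm.bootstrap_se(
            lambda Xb, yb: fit_logistic_quantile(Xb, yb, b), X, y, n_boot=60, seed=9
        )
        assert abs(m.intercept - 0.5) < 3 * se["const"]
        assert abs(m.coefficients["x1"] - 0.02) < 3 * se["x1"]

    def test_constant_outcome_at_midpoint_gives_zero_fit(self):
        b = fm.TransformBounds(0.0, 1.0)
        X = np.column_stack([np.ones(9), np.arange(9.0)])
        y = np.full(9, 0.5)
        m = fit_logistic_quantile(X, y, b)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.coefficients["x1"] == pytest.approx(0.0, abs=1e-9)

    def test_out_of_bounds_outcome_named(self):
        b = fm.TransformBounds(0.0, 1.0)
        X = np.ones((3, 1))
        with pytest.raises(TransformDomainError):
            fit_logistic_quantile(X, np.array([0.5, 1.0, 0.2]), b)


class TestPredictAndRegistry:
    def test_zero_profile_returns_published_intercept(self):
        m = fm.published_mapping("ols", 4)
        assert fm.predict(m, fm.SubscaleProfile(0, 0, 0, 0, 0)) == pytest.approx(0.2846)

    def test_mean_profile_prediction(self):
        m = fm.published_mapping("ols", 4)
        pred = fm.predict(m, fm.SubscaleProfile(21.1, 22.2, 18.0, 20.0, 21.7))
        assert round(pred, 4) == 0.7755

    def test_published_registry_cells(self):
        m = fm.published_mapping("ols", 4)
        assert m.intercept == 0.2846
        assert m.coefficients == {"PWB": 0.0121, "EWB": 0.0041, "FWB": 0.0044, "BCS": 0.0034}
        t5 = fm.published_mapping("tobit", 5)
        assert t5.intercept == 0.2318
        assert t5.coefficients == {"PWB": 0.0152, "EWB": 0.0078, "FWB": 0.0054}

    @pytest.mark.parametrize("model_id", [1, 2, 3, 4, 5])
    def test_clad_and_quantile_published_estimates_identical(self, model_id):
        c = fm.published_mapping("clad", model_id)
        q = fm.published_mapping("quantile", model_id)
        assert c.intercept == q.intercept and c.coefficients == q.coefficients

    def test_unknown_pair_raises(self):
        with pytest.raises(RegistryLookupError):
            fm.published_mapping("ols", 9)
        with pytest.raises(RegistryLookupError):
            fm.published_mapping("ridge", 1)

    def test_lqr_registry_carries_bounds_and_bounded_predictions(self):
        m = fm.published_mapping("lqr", 4)
        assert m.bounds == fm.bounds_preset("japanese")
        rng = np.random.default_rng(0)
        profiles = pd.DataFrame(
            {s: rng.uniform(0, hi, 10_000) for s, hi in
             [("PWB", 28), ("EWB", 24), ("FWB", 28), ("BCS", 40)]}
        )
        pred = fm.predict(m, profiles)
        assert np.all((pred > m.bounds.y_min) & (pred < m.bounds.y_max))

    def test_missing_covariate_prediction_error(self):
        m = fm.published_mapping("ols", 4)
        with pytest.raises(UndefinedPredictionError):
            fm.predict(m, fm.SubscaleProfile(pwb=20.0))

    def test_json_round_trip(self, baseline_cohort):
        b = fm.derive_bounds(float(baseline_cohort.utility.min()), 0.01)
        m = fm.fit("lqr", baseline_cohort, 4, bounds=b)
        m2 = fm.FittedMapping.from_json(m.to_json())
        assert m2.method == "lqr" and m2.coefficients == m.coefficients
        assert m2.bounds.y_min == pytest.approx(b.y_min)
        some = baseline_cohort.data.iloc[:5]
        assert np.allclose(fm.predict(m2, some), fm.predict(m, some))

    def test_tobit_prediction_is_latent_index_and_may_exceed_one(self):
        m = fm.published_mapping("tobit", 4)
        top = fm.SubscaleProfile(28, 28, 24, 28, 40)
        assert fm.predict(m, top) > 1.0
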