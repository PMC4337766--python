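"""Mixed-model estimation, nested tests, slopes and predictions."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from dielmove import glmm
from dielmove.glmm import (
    DielMixedModel,
    GlmmSpec,
    build_design,
    fit_glmm,
    fit_model_suite,
    lrt,
    predict_response,
    rank_slopes,
    slope_percent_change,
)
from dielmove.recovery import recovery_experiment
from dielmove.synthetic import (
    DD_COEFFICIENTS,
    MP_COEFFICIENTS,
    SimulationConfig,
    assign_ranks,
    simulate_daily_responses,
    simulate_ndvi,
    truth_model_rows,
)


def simulated_rows(response, seed=0, n_days=500, **config_kwargs):
    config = SimulationConfig(seed=seed, n_days=n_days, **config_kwargs)
    rng = np.random.default_rng(seed)
    ndvi = simulate_ndvi(n_days, rng)
    truth = simulate_daily_responses(config, ndvi, assign_ranks(config), rng)
    return truth_model_rows(truth, response)


def simple_binomial_rows(seed=1, n_groups=8, n_per=120, sigma=0.4):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, sigma)
        x = rng.uniform(0, 1, n_per)
        p = expit(-1.0 + 2.0 * x + b)
        y = rng.binomial(24, p) / 24.0
        rows.append(pd.DataFrame({"individual_id": f"G{g}", "ndvi": x, "y": y}))
    return pd.concat(rows, ignore_index=True)


class TestDesignMatrix:
    def test_columns_and_reference_level(self):
        rows = simulated_rows("dd", seed=3, n_days=365)
        X, y, groups = build_design(rows, GlmmSpec("dd"))
        assert list(X.columns) == [
            "Intercept", "ndvi", "rank[medium]", "rank[variable]", "rank[high]",
            "ndvi:rank[medium]", "ndvi:rank[variable]", "ndvi:rank[high]",
            "lag1", "lag2",
        ]
        assert len(y) == len(groups) == len(rows)

    def test_collinear_terms_named(self):
        rows = simulated_rows("dd", seed=3, n_days=365)
        rows["lag2"] = rows["lag1"]
        with pytest.raises(ValueError, match="collinear"):
            build_design(rows, GlmmSpec("dd"))


class TestZeroVarianceEquivalence:
    def test_binomial_forced_zero_matches_glm(self):
        rows = simple_binomial_rows(sigma=0.0)
        fit = fit_glmm(rows, GlmmSpec("mp", terms=("ndvi",)), force_zero_re=True)
        counts = np.rint(rows["y"] * 24)
        X = sm.add_constant(rows["ndvi"])
        ref = sm.GLM(
            np.column_stack([counts, 24 - counts]), X, family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)

    def test_linear_boundary_matches_ols(self):
        # residuals centered within groups force the variance to the boundary
        rng = np.random.default_rng(5)
        n, g = 600, 6
        x = rng.uniform(0, 1, n)
        groups = np.repeat([f"G{i}" for i in range(g)], n // g)
        eps = rng.normal(0, 1.0, n)
        for lab in np.unique(groups):
            eps[groups == lab] -= eps[groups == lab].mean()
        rows = pd.DataFrame(
            {"individual_id": groups, "ndvi": x, "y": 2.0 + 1.5 * x + eps}
        )
        fit = fit_glmm(rows, GlmmSpec("dd", terms=("ndvi",)))
        ols = sm.OLS(rows["y"], sm.add_constant(rows["ndvi"])).fit()
        assert fit.re_var == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-4)


class TestParameterRecovery:
    @pytest.mark.parametrize("response", ["dd", "mp"])
    def test_estimates_within_three_se(self, response):
        truth = DD_COEFFICIENTS if response == "dd" else MP_COEFFICIENTS
        hits, total = 0, 0
        for seed in (21, 22, 23):
            rows = simulated_rows(response, seed=seed, n_days=600)
            fit = fit_glmm(rows, GlmmSpec(response))
            assert fit.converged
            z = (fit.params - truth.reindex(fit.params.index)) / fit.bse
            hits += int((z.abs() <= 3.0).sum())
            total += len(z)
        assert hits / total >= 0.9

    def test_recovery_experiment_mp_short(self):
        res = recovery_experiment("mp", n_seeds=2, seed=11, n_days=500)
        assert abs(res.slopes["low"] - MP_COEFFICIENTS["ndvi"]) < 0.5
        assert res.per_seed["converged"].all()


class TestLrt:
    def test_identical_models(self):
        rows = simple_binomial_rows()
        fit = fit_glmm(rows, GlmmSpec("mp", terms=("ndvi",)))
        res = lrt(fit, fit)
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_interaction_df_three(self):
        rows = simulated_rows("dd", seed=6, n_days=365)
        full = fit_glmm(rows, GlmmSpec("dd"))
        red = fit_glmm(rows, GlmmSpec("dd", ("ndvi", "rank", "lag1", "lag2")))
        res = lrt(full, red)
        assert res.df == 3
        assert res.chi2 >= -1e-6

    def test_nested_loglik_monotone(self):
        rows = simulated_rows("dd", seed=7, n_days=365)
        suite = fit_model_suite(rows, "dd")
        fits = suite["fits"]
        assert fits["full"].loglik >= fits["no_interaction"].loglik - 1e-6
        assert fits["no_interaction"].loglik >= fits["null"].loglik - 1e-6
        assert fits["full"].loglik >= fits["lag1_only"].loglik - 1e-6

    def test_non_nested_rejected(self):
        rows = simulated_rows("dd", seed=6, n_days=365)
        a = fit_glmm(rows, GlmmSpec("dd", ("ndvi", "lag1")))
        b = fit_glmm(rows, GlmmSpec("dd", ("ndvi", "rank")))
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)


class TestSlopes:
    def test_reference_dd_slopes(self):
        slopes = rank_slopes(DD_COEFFICIENTS)
        assert slopes == pytest.approx(
            {"low": 0.38, "medium": 0.33, "variable": 0.40, "high": 0.61}
        )

    def test_reference_mp_slopes(self):
        slopes = rank_slopes(MP_COEFFICIENTS)
        assert slopes == pytest.approx(
            {"low": 2.85, "medium": 2.07, "variable": 2.31, "high": 1.37}
        )

    @pytest.mark.parametrize(
        "slopes, expected",
        [
            ({"low": 0.38, "high": 0.61}, 61.0),
            ({"low": 2.85, "high": 1.37}, -52.0),
            ({"low": 0.5, "high": 0.5}, 0.0),
        ],
    )
    def test_percent_change(self, slopes, expected):
        assert slope_percent_change(slopes) == expected

    def test_zero_low_slope_rejected(self):
        with pytest.raises(ValueError):
            slope_percent_change({"low": 0.0, "high": 1.0})

    def test_no_interaction_means_equal_slopes(self):
        params = pd.Series(
            {"Intercept": 1.0, "ndvi": 0.4, "ndvi:rank[high]": 0.0, "ndvi:rank[medium]": 0.0}
        )
        slopes = rank_slopes(params)
        assert slopes["high"] == slopes["medium"] == slopes["low"]


class TestPredictions:
    def test_intercept_only_flat(self):
        rows = simulated_rows("dd", seed=8, n_days=365)
        fit = fit_glmm(rows, GlmmSpec("dd"))
        fit.params[:] = 0.0
        fit.params["Intercept"] = 3.0
        pred = predict_response(fit, np.linspace(0.1, 0.8, 5), (0.0, 0.0), "high")
        np.testing.assert_allclose(pred, 3.0)

    def test_logit_predictions_bounded(self):
        rows = simulated_rows("mp", seed=8, n_days=365)
        fit = fit_glmm(rows, GlmmSpec("mp"))
        pred = predict_response(fit, np.linspace(0.05, 0.9, 20), (0.5, 0.5), "low")
        assert ((pred > 0) & (pred < 1)).all()

    def test_curve_slopes_order_matches_rank_slopes(self):
        rows = simulated_rows("dd", seed=9, n_days=500)
        fit = fit_glmm(rows, GlmmSpec("dd"))
        slopes = rank_slopes(fit)
        grid = np.array([0.2, 0.7])
        curve_slope = {
            rank: np.diff(predict_response(fit, grid, (1.0, 1.0), rank))[0]
            for rank in slopes
        }
        order_a = sorted(slopes, key=slopes.get)
        order_b = sorted(curve_slope, key=curve_slope.get)
        assert order_a == order_b

    def test_outside_range_warns(self):
        rows = simulated_rows("dd", seed=8, n_days=365)
        fit = fit_glmm(rows, GlmmSpec("dd"))
        with pytest.warns(UserWarning, match="beyond the fitted range"):
            predict_response(fit, np.array([2.0]), (0.0, 0.0), "low")


class TestShiftEquivariance:
    def test_intercept_absorbs_constant_shift(self):
        rows = simulated_rows("dd", seed=10, n_days=500)
        fit = fit_glmm(rows, GlmmSpec("dd"))
        shifted = rows.copy()
        c = 5.0
        shifted[["y", "lag1", "lag2"]] += c
        fit2 = fit_glmm(shifted, GlmmSpec("dd"))
        expected = fit.params["Intercept"] + c * (1 - fit.params["lag1"] - fit.params["lag2"])
        assert fit2.params["Intercept"] == pytest.approx(expected, abs=1e-3)
        np.testing.assert_allclose(
            fit2.params.drop("Intercept"), fit.params.drop("Intercept"), atol=1e-3
        )


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = DielMixedModel(response="mp", n_quad_nodes=11)
        assert est.get_params()["n_quad_nodes"] == 11
        est.set_params(response="dd")
        assert est.response == "dd"

    def test_fit_exposes_attributes(self):
        rows = simulated_rows("dd", seed=12, n_days=365)
        est = DielMixedModel(response="dd").fit(rows)
        assert est.coef_.index.equals(est.bse_.index)
        assert est.re_var_ >= 0.0
        assert np.isfinite(est.loglik_)


R_GLMER = """
suppressMessages(library(lme4))
d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
d$succ <- round(d$y * 24); d$fail <- 24 - d$succ
m <- glmer(cbind(succ, fail) ~ ndvi + (1 | individual_id),
           data = d, family = binomial, nAGQ = 15)
cat(fixef(m)[1], fixef(m)[2], as.numeric(logLik(m)),
    as.numeric(VarCorr(m)$individual_id[1]), sep = ",")
"""


class TestAgainstLme4:
    def test_binomial_glmm_matches_glmer(self, tmp_path):
        rows = simple_binomial_rows(seed=2, n_groups=8, n_per=150, sigma=0.5)
        csv = tmp_path / "rows.csv"
        rows.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(R_GLMER)
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(csv)],
            capture_output=True, text=True, check=True,
        )
        b0, b1, ll, var = map(float, out.stdout.strip().split(","))
        fit = fit_glmm(rows, GlmmSpec("mp", terms=("ndvi",)))
        assert fit.params["Intercept"] == pytest.approx(b0, abs=2e-3)
        assert fit.params["ndvi"] == pytest.approx(b1, abs=2e-3)
        # glmer reports the log-likelihood relative to the saturated model;
        # shift ours onto the same scale before comparing
        from scipy.special import gammaln, xlogy

        y = np.rint(rows["y"] * 24)
        n = 24.0
        ll_sat = float(
            np.sum(
                xlogy(y, y / n) + xlogy(n - y, 1 - y / n)
                + gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            )
        )
        assert fit.loglik - ll_sat == pytest.approx(ll, abs=0.05)
        assert fit.re_var == pytest.approx(var, rel=0.05, abs=2e-3)
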