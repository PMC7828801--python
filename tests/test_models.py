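"""Tests for the design matrix, model grid, HMC fits and risk summaries."""

import copy
import math

import numpy as np
import pandas as pd
import pytest

import dismap as dm
from dismap.models import (
    build_design,
    classify_rr,
    fit_model,
    make_model_grid,
    model_spec,
    posterior_mode,
    propagate_priors,
    summarize_rr,
)


class TestDesign:
    def test_pm_centring_and_scaling(self, small_bundle, small_design):
        assert abs(small_design.X[:, 1].mean()) < 1e-9
        # a value 15 ug/m3 above the grand mean codes to exactly +1
        grand = small_bundle.exposure["pm25"].mean()
        row = np.argmax(small_bundle.exposure["pm25"].to_numpy())
        expected = (small_bundle.exposure["pm25"].iloc[row] - grand) / 15.0
        m = small_bundle.exposure.iloc[row]
        mask = (small_design.area_index == m["area_id"]) & (
            small_design.years == m["year"]
        )
        assert small_design.X[mask, 1][0] == pytest.approx(expected)

    def test_rural_indicator_merges_peri_urban(self, small_bundle, small_design):
        deg = small_bundle.lattice.degurba[small_design.area_index]
        assert set(np.unique(small_design.X[:, 2])) <= {0.0, 1.0}
        assert (small_design.X[:, 2] == (deg == "rural").astype(float)).all()

    def test_trend_column_counts_years_from_start(self, small_bundle):
        d = build_design(small_bundle, trend=True)
        assert d.columns[-1] == "year_c"
        assert set(np.unique(d.X[:, 3])) == {0.0, 1.0}

    def test_zero_expected_count_rejected(self, small_bundle):
        expected = dm.compute_expected_counts(
            small_bundle.population, small_bundle.deaths_strata
        )
        expected.loc[0, "e"] = 0.0
        with pytest.raises(ValueError):
            build_design(small_bundle, expected=expected)


class TestModelGrid:
    def test_grid_has_eight_cells(self):
        grid = make_model_grid()
        assert len(grid) == 8
        assert [s.grid_id for s in grid] == list(
            ("M1A", "M1B", "M2A", "M2B", "M3A", "M3B", "M4A", "M4B")
        )

    def test_m4a_is_bym_without_trend(self):
        spec = model_spec("M4A")
        assert spec.random == "bym" and spec.trend is False
        assert set(spec.var_priors) == {"iid", "icar"}

    def test_default_coefficient_prior_sd_is_three(self):
        for spec in make_model_grid():
            assert all(sd == 3.0 and m == 0.0 for m, sd in spec.coef_priors.values())


class TestFits:
    def test_null_data_recovers_flat_intercept(self, small_lattice):
        pop = dm.generate_population(small_lattice, years=[2010], seed=1)
        exp = dm.generate_exposure_field(small_lattice, years=[2010], seed=2)
        bundle = dm.StudyBundle(
            lattice=small_lattice, years=(2010,), population=pop, exposure=exp
        )
        bundle = dm.generate_outcomes(
            bundle, beta_pm=0.0, beta_rural=0.0, re_kind="none", seed=3
        )
        fit = fit_model(
            model_spec("M1A"), build_design(bundle), chains=2, draws=400,
            warmup=400, seed=0,
        )
        beta0 = fit.stacked("beta")[:, 0]
        assert abs(beta0.mean()) < 3 * beta0.std(ddof=1)

    def test_offset_shift_moves_intercept(self, small_design):
        """Doubling every expected count shifts beta0 by -log 2."""
        fit_a = fit_model(model_spec("M1A"), small_design, chains=2, draws=400,
                          warmup=400, seed=1)
        shifted = copy.copy(small_design)
        shifted.offset = small_design.offset + math.log(2.0)
        fit_b = fit_model(model_spec("M1A"), shifted, chains=2, draws=400,
                          warmup=400, seed=1)
        a = fit_a.stacked("beta")[:, 0]
        b = fit_b.stacked("beta")[:, 0]
        se = math.hypot(a.std(ddof=1) / np.sqrt(200), b.std(ddof=1) / np.sqrt(200))
        assert b.mean() - a.mean() == pytest.approx(-math.log(2.0), abs=max(6 * se, 0.01))

    def test_icar_effects_sum_to_zero(self, small_design, small_weights):
        fit = fit_model(model_spec("M3A"), small_design, weights=small_weights,
                        chains=2, draws=300, warmup=300, seed=2)
        assert abs(fit.stacked("s").mean(axis=0).sum()) < 1e-8

    def test_flat_prior_mode_matches_glm(self, small_design):
        sm = pytest.importorskip("statsmodels.api")
        mode = posterior_mode(model_spec("M1A", coef_sd=30.0), small_design)
        glm = sm.GLM(
            small_design.y, small_design.X, family=sm.families.Poisson(),
            offset=small_design.offset,
        ).fit()
        for k, c in enumerate(small_design.columns):
            assert mode[c] == pytest.approx(glm.params[k], abs=0.01)

    def test_disconnected_graph_rejected_for_icar(self, small_design):
        from dismap.spatial import SpatialWeights

        w = SpatialWeights.from_edges(small_design.n_areas, [(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            fit_model(model_spec("M3A"), small_design, weights=w, chains=2,
                      draws=50, warmup=50, seed=0)

    def test_reference_fit_converges(self, m2a_fit):
        """The shipped example configuration passes the Rhat gate."""
        assert m2a_fit.max_rhat < 1.01
        assert m2a_fit.converged
        assert m2a_fit.loglik.shape[2] == m2a_fit.design.n_obs


class TestPriorPropagation:
    def test_posterior_becomes_next_prior(self, m2a_fit):
        nxt = propagate_priors(m2a_fit, model_spec("M3A"))
        beta = m2a_fit.stacked("beta")
        for k, c in enumerate(m2a_fit.design.columns):
            mean, sd = nxt.coef_priors[c]
            assert mean == pytest.approx(beta[:, k].mean())
            assert sd == pytest.approx(beta[:, k].std(ddof=1))

    def test_variance_hyperprior_recentred(self, m2a_fit):
        nxt = propagate_priors(m2a_fit, model_spec("M4A"))
        m = float(np.median(m2a_fit.stacked("sigma2_iid")))
        assert nxt.var_priors["iid"] == {"family": "inverse_gamma", "a": 4.0, "b": 3.0 * m}
        # the ICAR component had no counterpart: default prior kept
        assert nxt.var_priors["icar"] == {"family": "inverse_gamma", "a": 0.01, "b": 0.01}

    def test_unconverged_fit_refused(self, m2a_fit):
        bad = copy.copy(m2a_fit)
        bad.converged = False
        bad.max_rhat = 1.2
        with pytest.raises(ValueError):
            propagate_priors(bad, model_spec("M3A"))

    def test_informative_priors_shrink_collinear_coefficient(
        self, small_design, small_weights
    ):
        """Tight propagated priors reduce the posterior SD of the PM effect
        in the spatially structured model (collinearity control)."""
        default = model_spec("M3A")
        informative = model_spec("M3A")
        informative.coef_priors["pm25_c"] = (math.log(1.075), 0.02)
        f_def = fit_model(default, small_design, weights=small_weights, chains=2,
                          draws=400, warmup=400, seed=3)
        f_inf = fit_model(informative, small_design, weights=small_weights, chains=2,
                          draws=400, warmup=400, seed=3)
        sd_def = f_def.stacked("beta")[:, 1].std(ddof=1)
        sd_inf = f_inf.stacked("beta")[:, 1].std(ddof=1)
        assert sd_inf < sd_def


class TestRiskSummary:
    def test_constant_unit_draws_are_neutral(self):
        med, pp, cls = classify_rr(np.ones(1000))
        assert (med, pp, cls) == (1.0, 0.0, "neutral")

    def test_enumerated_draws(self):
        med, pp, cls = classify_rr(np.array([0.5, 1.5, 1.5, 1.5]))
        assert med == 1.5 and pp == 0.75 and cls == "neutral"

    def test_classification_boundaries(self):
        draws = np.concatenate([np.full(95, 2.0), np.full(5, 0.5)])
        assert classify_rr(draws)[2] == "high"
        draws = np.concatenate([np.full(5, 2.0), np.full(95, 0.5)])
        assert classify_rr(draws)[2] == "low"
        # pp exactly at a boundary stays neutral (strict inequalities)
        draws = np.concatenate([np.full(90, 2.0), np.full(10, 0.5)])
        assert classify_rr(draws)[2] == "neutral"

    def test_summary_table_shape_and_bounds(self, m2a_fit):
        out = summarize_rr(m2a_fit)
        d = m2a_fit.design
        assert len(out) == d.n_obs
        assert out["pp"].between(0, 1).all()
        assert set(out["risk_class"]) <= {"high", "low", "neutral"}
        assert (out["rr_median"] > 0).all()
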