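"""Tests for the synthetic study-bundle generators."""

import math

import numpy as np
import pandas as pd
import pytest

import dismap as dm
from dismap.spatial import SpatialWeights, morans_i
from dismap.synthetic import largest_remainder


class TestLattice:
    def test_invariants_over_seeds(self):
        """Adjacency symmetric/irreflexive, graph connected, subareas contiguous."""
        for seed in range(100):
            lat = dm.generate_lattice(24, (8, 7, 9), seed=seed)
            lat.validate()  # raises on any violated invariant
            assert all(i < j for i, j in lat.adjacency)

    def test_full_scale_lattice(self):
        lat = dm.generate_lattice(188, (53, 58, 77), seed=0)
        counts = pd.Series(lat.subarea).value_counts()
        assert counts["A"] == 53 and counts["B"] == 58 and counts["C"] == 77
        assert (pd.Series(lat.degurba) != "rural").sum() == 28
        lat.validate()

    def test_single_area_has_no_neighbours(self):
        lat = dm.generate_lattice(1, (1,), seed=0)
        assert lat.adjacency == set()

    def test_2x2_rook_grid_degrees(self):
        lat = dm.generate_lattice(4, (4,), seed=0, geometry="grid", n_urban=0)
        assert (lat.degrees() == 2).all()

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dm.generate_lattice(10, (3, 3, 3), seed=0)


class TestPopulation:
    def test_male_share_and_schema(self, small_lattice):
        pop = dm.generate_population(small_lattice, years=[2012], seed=1)
        male = pop.loc[pop.gender == "M", "count"].sum()
        assert abs(male - 258_596) / 258_596 < 0.005
        cells = pop.groupby(["area_id", "year"]).size()
        assert (cells == 40).all()
        assert (pop["count"] >= 0).all()

    def test_dominant_area_share(self, small_lattice):
        pop = dm.generate_population(small_lattice, years=[2012], seed=0)
        by_area = pop.groupby("area_id")["count"].sum()
        assert 0.10 <= by_area.max() / by_area.sum() <= 0.15

    def test_population_constant_across_years(self, small_lattice):
        pop = dm.generate_population(small_lattice, years=[2010, 2011], seed=2)
        y0 = pop[pop.year == 2010].drop(columns="year").reset_index(drop=True)
        y1 = pop[pop.year == 2011].drop(columns="year").reset_index(drop=True)
        pd.testing.assert_frame_equal(y0, y1)

    def test_largest_remainder_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.uniform(size=17)
            total = int(rng.integers(1, 10_000))
            alloc = largest_remainder(w, total)
            assert alloc.sum() == total and (alloc >= 0).all()


class TestExposure:
    def test_default_calibration_2012(self, small_lattice):
        exp = dm.generate_exposure_field(small_lattice, years=[2012], seed=5)
        x = exp["pm25"].to_numpy()
        assert abs(x.mean() - 23.58) < 0.5
        assert abs(x.std() - 6.49) < 0.5
        assert (x > 0).all()

    def test_pure_noise_limit(self, small_lattice):
        w = SpatialWeights.from_lattice(small_lattice)
        vals = []
        for seed in range(20):
            exp = dm.generate_exposure_field(
                small_lattice, years=[2012], seed=seed, spatial_range=0.0
            )
            vals.append(morans_i(exp["pm25"].to_numpy(), w))
        n = small_lattice.n_areas
        assert abs(np.mean(vals) - (-1 / (n - 1))) < 0.1

    def test_high_range_strong_autocorrelation(self):
        lat = dm.generate_lattice(188, (53, 58, 77), seed=0)
        w = SpatialWeights.from_lattice(lat)
        vals = [
            morans_i(
                dm.generate_exposure_field(lat, years=[2012], seed=s)["pm25"].to_numpy(),
                w,
            )
            for s in range(5)
        ]
        assert np.mean(vals) >= 0.90

    def test_moran_monotone_in_spatial_range(self, small_lattice):
        w = SpatialWeights.from_lattice(small_lattice)
        means = []
        for sr in (0.0, 0.5, 0.985):
            vals = [
                morans_i(
                    dm.generate_exposure_field(
                        small_lattice, years=[2012], seed=s, spatial_range=sr
                    )["pm25"].to_numpy(),
                    w,
                )
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_disconnected_lattice_rejected(self):
        lat = dm.generate_lattice(4, (4,), seed=0, geometry="grid", n_urban=0)
        lat.adjacency = {(0, 1), (2, 3)}  # two components
        with pytest.raises(ValueError):
            dm.generate_exposure_field(lat, years=[2012], seed=0)


class TestOutcomes:
    def test_null_model_conserves_totals(self, small_lattice):
        pop = dm.generate_population(small_lattice, years=[2010], seed=1)
        exp = dm.generate_exposure_field(small_lattice, years=[2010], seed=2)
        bundle = dm.StudyBundle(
            lattice=small_lattice, years=(2010,), population=pop, exposure=exp
        )
        out = dm.generate_outcomes(
            bundle, beta0=0, beta_pm=0, beta_rural=0, beta_year=0,
            re_kind="none", seed=3,
        )
        e_true = sum(out.truth["expected_baseline"].values())
        total = out.deaths["deaths"].sum()
        assert abs(total - e_true) < 3 * math.sqrt(e_true)

    def test_poisson_glm_recovers_pm_effect(self, small_lattice):
        """Oracle: ML Poisson regression on the simulated data, 20 replicates."""
        sm = pytest.importorskip("statsmodels.api")
        truth = math.log(1.075)
        pop = dm.generate_population(small_lattice, years=[2010, 2011], seed=1)
        estimates = []
        for r in range(20):
            exp = dm.generate_exposure_field(
                small_lattice, years=[2010, 2011], seed=100 + r
            )
            bundle = dm.StudyBundle(
                lattice=small_lattice, years=(2010, 2011), population=pop, exposure=exp
            )
            out = dm.generate_outcomes(
                bundle, beta_pm=truth, beta_rural=0.0, re_kind="none", seed=200 + r
            )
            e_true = pd.Series(out.truth["expected_baseline"]).rename("e")
            e_true.index = e_true.index.astype(int)
            m = out.deaths.merge(out.exposure, on=["area_id", "year"])
            m["e"] = m["area_id"].map(e_true)
            pm_c = (m["pm25"] - out.exposure["pm25"].mean()) / 15.0
            X = np.column_stack([np.ones(len(m)), pm_c])
            fit = sm.GLM(
                m["deaths"], X, family=sm.families.Poisson(),
                offset=np.log(m["e"]),
            ).fit()
            estimates.append(np.asarray(fit.params)[1])
        assert abs(np.mean(estimates) - truth) < 0.02

    def test_bym_effects_add_overdispersion(self, small_lattice):
        pop = dm.generate_population(small_lattice, years=[2010], seed=1)
        exp = dm.generate_exposure_field(small_lattice, years=[2010], seed=2)
        bundle = dm.StudyBundle(
            lattice=small_lattice, years=(2010,), population=pop, exposure=exp
        )

        def dispersion(re_kind):
            vals = []
            for s in range(10):
                out = dm.generate_outcomes(
                    bundle, beta_pm=0, beta_rural=0, re_kind=re_kind,
                    re_sd=0.3, re_sd_icar=0.3, seed=50 + s,
                )
                e = pd.Series(out.truth["expected_baseline"])
                e.index = e.index.astype(int)
                ratio = out.deaths.set_index("area_id")["deaths"] / e
                vals.append(ratio.var() / ratio.mean())
            return np.mean(vals)

        assert dispersion("bym") > dispersion("none")

    def test_same_seed_round_trips(self):
        b1 = dm.make_bundle(n_areas=20, subarea_sizes=(7, 6, 7), years=[2010], seed=9)
        b2 = dm.make_bundle(n_areas=20, subarea_sizes=(7, 6, 7), years=[2010], seed=9)
        pd.testing.assert_frame_equal(b1.deaths, b2.deaths)
        pd.testing.assert_frame_equal(b1.population, b2.population)
        pd.testing.assert_frame_equal(b1.exposure, b2.exposure)
        assert b1.truth == b2.truth
        assert b1.lattice.adjacency == b2.lattice.adjacency


class TestExceedance:
    def test_counts_and_percentages(self):
        exp = pd.DataFrame(
            {"area_id": list(range(188)), "year": 2014,
             "pm25": [30.0] * 4 + [10.0] * 184}
        )
        out = dm.exceedance_summary(exp, limit=25.0)
        assert out.loc[0, "n_exceeding"] == 4
        assert out.loc[0, "pct"] == pytest.approx(4 / 188 * 100, abs=1e-9)

    def test_all_below_and_all_above(self):
        exp = pd.DataFrame({"area_id": [0, 1, 2], "year": 2010, "pm25": 10.0})
        assert dm.exceedance_summary(exp, limit=25.0).loc[0, "n_exceeding"] == 0
        assert dm.exceedance_summary(exp, limit=5.0).loc[0, "n_exceeding"] == 3

    def test_strict_inequality_at_limit(self):
        exp = pd.DataFrame({"area_id": [0], "year": 2010, "pm25": 25.0})
        assert dm.exceedance_summary(exp, limit=25.0).loc[0, "n_exceeding"] == 0
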