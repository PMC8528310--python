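"""Scenario engine: SLR curves, spin-up, forward runs, Monte Carlo, and
DEM projection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tidalmarsh import engine, synth
from tidalmarsh.engine import (
    MarshModel,
    SeaLevelExtras,
    Trajectory,
    build_slr_curve,
    default_z0_grid_m,
    monte_carlo,
    project_dem,
    run_scenario,
    sediment_concentration,
    spin_up,
    threshold_sweep,
)
from tidalmarsh.vegetation import SalinityScenario


class TestSLRCurves:
    def test_totals(self):
        for name, total in [("low", 29), ("int_low", 39), ("mid", 99), ("high", 167)]:
            c = build_slr_curve(name)
            assert c[0] == 0.0
            assert c[-1] == pytest.approx(total)

    def test_linear_scenario_rates(self):
        # 29 cm over 85 yr = 3.4 mm/yr; 39 cm = 4.6 mm/yr
        low = np.diff(build_slr_curve("low")) * 10.0
        int_low = np.diff(build_slr_curve("int_low")) * 10.0
        assert low.mean() == pytest.approx(3.4, abs=0.05)
        assert low.std() < 1e-12
        assert int_low.mean() == pytest.approx(4.6, abs=0.05)

    def test_nonlinear_increments_strictly_increasing(self):
        for name in ("mid", "high"):
            inc = np.diff(build_slr_curve(name))
            assert np.all(np.diff(inc) > 0)

    def test_unknown_scenario(self):
        with pytest.raises(KeyError):
            build_slr_curve("extreme")

    def test_override_curve(self):
        c = np.linspace(0, 50, 86)
        s = engine.SLRScenario("low", curve_cm=c)
        assert np.allclose(s.build(), c)


class TestSedimentScenarios:
    def test_rules(self):
        C0 = 100.0
        assert sediment_concentration("historic", C0, 10) == 100.0
        assert sediment_concentration("constant", C0, 10) == 60.0
        assert sediment_concentration("increasing", C0, 10) == 125.0
        dec = sediment_concentration("declining", C0, 10)
        assert dec == pytest.approx(60.0 * (1 - 0.016) ** 10)
        assert sediment_concentration("declining", C0, 0) == 60.0

    def test_unknown_kind(self):
        with pytest.raises(KeyError):
            sediment_concentration("wet", 10.0, 0)


class TestExtras:
    def test_deterministic_for_seed(self):
        a = SeaLevelExtras(seed=4).sea_level_offsets(60)
        b = SeaLevelExtras(seed=4).sea_level_offsets(60)
        assert np.array_equal(a, b)

    def test_disabled_is_zero(self):
        assert np.all(SeaLevelExtras(enabled=False).sea_level_offsets(40) == 0)

    def test_amplitude_bounds(self):
        off = SeaLevelExtras(seed=0).sea_level_offsets(200)
        assert np.all(np.abs(off) <= 2.0 + 5.0 + 1e-9)


class TestSpinUp:
    def test_equilibrium_contract(self, browns_model, spun_browns):
        col, state, rate = spun_browns
        # re-running 200 years at the solved rate leaves elevation within
        # the bisection tolerance of the start
        fresh = browns_model.initial_column(42.0)
        st = browns_model.initial_cover(42.0)
        browns_model.run_years(fresh, st, np.full(200, browns_model.site.ssc_mg_l), np.full(200, rate / 10.0))
        assert abs(fresh.surface_elevation - 42.0) < 0.1

    def test_rate_decreases_with_starting_elevation(self, browns_model):
        rates = [spin_up(browns_model, z0)[2] for z0 in (30.0, 60.0, 90.0)]
        assert rates[0] > rates[1] > rates[2]

    def test_inert_configuration_equilibrates_at_zero(self):
        site = synth.site_params("browns_island", ssc_mg_l=0.0)
        species = synth.species_set("browns_island", site.tide_range_m, o_scale=0.0)
        model = MarshModel(site, species, tide=synth.make_model("browns_island").tide)
        _, _, rate = spin_up(model, 60.0)
        assert rate < 0.05


class TestRunScenario:
    def test_same_seed_identical_trajectory(self, browns_model, spun_browns):
        col, state, _ = spun_browns
        kw = dict(
            slr="mid",
            sediment="constant",
            salinity=SalinityScenario(0.2),
            extras=SeaLevelExtras(seed=9),
            seed=9,
        )
        t1 = run_scenario(browns_model, (col, state), **kw)
        t2 = run_scenario(browns_model, (col, state), **kw)
        assert np.array_equal(t1.elevation_cm, t2.elevation_cm)
        assert np.array_equal(t1.car_g_m2_yr, t2.car_g_m2_yr)
        assert np.array_equal(t1.cover, t2.cover)

    def test_high_slr_ends_lower_than_low(self, browns_model, spun_browns):
        col, state, _ = spun_browns
        hi = run_scenario(browns_model, (col, state), slr="high")
        lo = run_scenario(browns_model, (col, state), slr="low")
        assert hi.elevation_cm[-1] < lo.elevation_cm[-1]

    def test_inert_marsh_is_a_fixed_point(self):
        site = synth.site_params("browns_island", ssc_mg_l=0.0)
        species = synth.species_set("browns_island", site.tide_range_m, o_scale=0.0)
        model = MarshModel(site, species, tide=synth.make_model("browns_island").tide)
        col = model.initial_column(60.0)
        state = model.initial_cover(60.0)
        traj = model.run_years(col, state, np.zeros(85), np.zeros(85))
        assert np.all(np.abs(traj.elevation_cm - 60.0) < 1e-9)

    def test_budget_closure_every_year(self, browns_model, spun_browns):
        col, state, _ = spun_browns
        t = run_scenario(browns_model, (col, state), slr="mid")
        delta = np.diff(t.elevation_cm)
        assert np.allclose(delta, t.mar_cm + t.oar_cm - t.decomp_cm - t.slr_cm, atol=1e-9)

    def test_trajectory_frame_schema(self, browns_model, spun_browns):
        col, state, _ = spun_browns
        t = run_scenario(browns_model, (col, state), slr="low", n_years=10)
        df = t.to_frame()
        assert len(df) == 10
        assert {"year", "elevation_cm", "car_g_m2_yr", "total_cover", "state"} <= set(df.columns)


class TestMonteCarlo:
    def _zero_sd_model(self, browns_model):
        site = dataclasses.replace(
            browns_model.site,
            ssc_sd=0.0,
            organic_scaler_sd=0.0,
            decomp=dataclasses.replace(browns_model.site.decomp, A_sd=0.0),
        )
        m = MarshModel(site, browns_model.species, tide=browns_model.tide)
        m._tables = browns_model._tables
        return m

    def test_zero_sd_collapses_to_deterministic_run(self, browns_model, spun_browns):
        col, state, _ = spun_browns
        m = self._zero_sd_model(browns_model)
        trajs, summary, _ = monte_carlo(
            m, (col, state), n=8, seed=2, slr="low",
            salinity=SalinityScenario(0.0, omega=0.027, omega_sd=0.0),
        )
        # draws are bitwise identical (summary SD only carries the ~1 ulp
        # rounding of the axis-mean)
        for t in trajs[1:]:
            assert np.array_equal(t.elevation_cm, trajs[0].elevation_cm)
        assert np.all(summary["elev_sd_cm"] < 1e-10)
        single = run_scenario(m, (col, state), slr="low")
        assert np.allclose(trajs[0].elevation_cm, single.elevation_cm)

    def test_seed_reproducibility_and_spread_growth(self, browns_model, spun_browns):
        col, state, _ = spun_browns
        kw = dict(n=12, seed=7, slr="mid", sediment="constant")
        _, s1, p1 = monte_carlo(browns_model, (col, state), **kw)
        _, s2, p2 = monte_carlo(browns_model, (col, state), **kw)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(p1, p2)
        # parameter uncertainty compounds with horizon
        assert s1["elev_sd_cm"].iloc[-1] >= s1["elev_sd_cm"].iloc[14]

    def test_parameter_log_within_one_sd(self, browns_model, spun_browns):
        col, state, _ = spun_browns
        _, _, params = monte_carlo(browns_model, (col, state), n=10, seed=3, slr="low")
        site = browns_model.site
        assert params["C0_mg_l"].between(site.ssc_mg_l - site.ssc_sd, site.ssc_mg_l + site.ssc_sd).all()
        for j, a in enumerate(site.decomp.A, start=1):
            assert params[f"A{j}"].between(a - site.decomp.A_sd, a + site.decomp.A_sd).all()


class TestThresholdSweep:
    def test_persistence_monotone_and_reported(self, browns_model):
        table, thr = threshold_sweep(
            browns_model, 42.0, rates_mm_yr=np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        )
        persisted = table["persisted"].to_numpy()
        # once the marsh drowns at a rate it drowns at all higher rates
        assert np.all(np.diff(persisted.astype(int)) <= 0)
        if thr is not None:
            assert not table.loc[table["rate_mm_yr"] >= thr, "persisted"].any()


class TestProjectDem:
    def _fake_traj(self, z0_cm, slope, n=10):
        elev = z0_cm + slope * np.arange(n + 1, dtype=float)
        cover = np.full((n, 1), 1.0 if z0_cm > 0 else 0.05)
        return Trajectory(
            years=np.arange(1, n + 1),
            elevation_cm=elev,
            sea_level_cm=np.zeros(n + 1),
            car_g_m2_yr=np.zeros(n),
            mar_cm=np.zeros(n),
            oar_cm=np.zeros(n),
            decomp_cm=np.zeros(n),
            slr_cm=np.zeros(n),
            cover=cover,
            species_names=["sp"],
        )

    def test_pixel_on_grid_node_gets_trajectory_verbatim(self):
        trajs = {0.0: self._fake_traj(0.0, -1.0), 1.0: self._fake_traj(100.0, 1.0)}
        dem = np.full((4, 4), 1.0)
        summary, stack = project_dem(dem, trajs, return_rasters=True)
        assert np.allclose(stack[-1][np.isfinite(stack[-1])], trajs[1.0].elevation_cm[-1])

    def test_constant_dem_mean_equals_trajectory(self):
        trajs = {0.0: self._fake_traj(0.0, 0.0), 1.0: self._fake_traj(100.0, 2.0)}
        dem = np.full((5, 5), 0.5)
        summary, _ = project_dem(dem, trajs)
        mid = 0.5 * (trajs[0.0].elevation_cm + trajs[1.0].elevation_cm)
        assert np.allclose(summary["elev_mean_cm"], mid)
        assert np.all(summary["elev_sd_cm"] == 0.0)

    def test_interpolation_bounded_by_bracketing_bins(self):
        trajs = {0.0: self._fake_traj(0.0, -2.0), 1.0: self._fake_traj(100.0, 3.0)}
        rng = np.random.default_rng(0)
        dem = rng.uniform(0.0, 1.0, (6, 6))
        _, stack = project_dem(dem, trajs, return_rasters=True)
        lo = min(trajs[0.0].elevation_cm[-1], trajs[1.0].elevation_cm[-1])
        hi = max(trajs[0.0].elevation_cm[-1], trajs[1.0].elevation_cm[-1])
        vals = stack[-1][np.isfinite(stack[-1])]
        assert np.all((vals >= lo - 1e-9) & (vals <= hi + 1e-9))

    def test_out_of_range_pixels_masked_and_counted(self):
        trajs = {0.0: self._fake_traj(0.0, 0.0), 1.0: self._fake_traj(100.0, 0.0)}
        dem = np.array([[0.5, 3.0], [np.nan, 0.2]])
        summary, stack = project_dem(dem, trajs, return_rasters=True)
        assert summary["n_valid"].iloc[0] == 2
        assert summary["n_masked"].iloc[0] == 2
        assert np.isnan(stack[0][0, 1]) and np.isnan(stack[0][1, 0])

    def test_mudflat_fraction_from_interpolated_cover(self):
        trajs = {0.0: self._fake_traj(-10.0, 0.0), 1.0: self._fake_traj(100.0, 0.0)}
        dem = np.array([[0.05, 0.95]])
        summary, _ = project_dem(dem, trajs)
        assert summary["mudflat_fraction"].iloc[0] == pytest.approx(0.5)

    def test_default_initial_elevation_grid(self):
        g = default_z0_grid_m()
        assert g[0] == pytest.approx(-0.5)
        assert g[-1] == pytest.approx(5.0)
        assert np.any(np.isclose(np.diff(g), 0.1)) and np.any(np.isclose(np.diff(g), 0.5))
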