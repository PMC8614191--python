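"""Synthetic study generator: determinism, geometric and statistical
structure, and dial-through of the generator knobs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from streamtherm.config import CoefficientTruth, HeatWave, SimConfig
from streamtherm.landscape import compute_bfi
from streamtherm.synthetic import (
    generate_climate,
    generate_discharge,
    generate_network,
    make_dataset,
)

from conftest import small_sim_config


class TestNetwork:
    def test_zero_meander_all_reaches_straight(self, rng):
        cfg = small_sim_config(meander_amplitude=0.0)
        net, _, _, _ = generate_network(cfg, rng)
        for r in net.reaches.values():
            assert r.sinuosity() == pytest.approx(1.0, abs=1e-12)

    def test_meandering_raises_sinuosity(self, rng):
        cfg = small_sim_config(meander_amplitude=150.0)
        net, _, _, _ = generate_network(cfg, np.random.default_rng(0))
        stems = [r for r in net.reaches.values() if "stem" in r.reach_id]
        assert max(r.sinuosity() for r in stems) > 1.02

    def test_drainage_area_monotone_downstream(self, rng):
        net, _, _, _ = generate_network(small_sim_config(), rng)
        net.validate()  # raises on any decrease

    def test_nested_sites_share_containment(self, rng):
        cfg = small_sim_config(n_sites=4, sites_per_basin=2)
        _, sites, catchments, _ = generate_network(cfg, rng)
        by_basin = sites.groupby("basin")["site"].apply(list)
        for basin_sites in by_basin:
            if len(basin_sites) < 2:
                continue
            polys = sorted((catchments[s] for s in basin_sites), key=lambda p: p.area)
            assert polys[0].within(polys[1].buffer(1e-6))
            assert polys[1].area > polys[0].area

    def test_outlet_drainage_equals_mask_cell_area(self, rng):
        """Catchment rectangles snap to the grid, so the rasterized mask
        area (cell count x cell area) reproduces the reported drainage
        area exactly."""
        cfg = small_sim_config()
        study = make_dataset(cfg, seed=11)
        from streamtherm.landscape import _rasterize

        for sid, (x, y) in study.network.sites.items():
            poly = study.catchments[sid]
            win = study.dem.window(*poly.bounds)
            mask = _rasterize(poly, win)
            mask_km2 = mask.sum() * cfg.cell_size**2 / 1e6
            reach = study.network.nearest_reach(x, y)
            da = study.network.reaches[reach].drainage_km2
            assert mask_km2 == pytest.approx(da, abs=1e-9)

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            small_sim_config(catchment_km2_range=(-1.0, 2.0)).validate()


class TestClimate:
    def test_zero_noise_no_waves_is_pure_sinusoid(self):
        cfg = small_sim_config(air_ar1_sd=0.0, heat_waves=[], diurnal_range_sd=0.0)
        elev = pd.Series({"S001": 200.0, "S002": 300.0})
        ta_max, ta_min = generate_climate(cfg, elev, np.random.default_rng(0))
        doy = ta_max.index.dayofyear.to_numpy()
        expected = cfg.air_mean + cfg.air_seasonal_amp * np.cos(
            2 * np.pi * (doy - 201) / 365.25
        )
        assert np.allclose(ta_max["S001"], expected, atol=1e-12)
        assert np.allclose(ta_max["S001"], ta_max["S002"], atol=1e-12)
        assert np.allclose(ta_max["S001"] - ta_min["S001"], cfg.diurnal_range_mean)

    def test_scheduled_wave_is_warmest_anomaly_of_its_year(self):
        cfg = small_sim_config(
            air_ar1_sd=0.0,
            diurnal_range_sd=0.0,
            heat_waves=[HeatWave("2015-07-17", amplitude=8.0)],
        )
        elev = pd.Series({"S001": 200.0})
        ta_max, _ = generate_climate(cfg, elev, np.random.default_rng(0))
        doy = ta_max.index.dayofyear.to_numpy()
        seasonal = cfg.air_mean + cfg.air_seasonal_amp * np.cos(
            2 * np.pi * (doy - 201) / 365.25
        )
        anom = pd.Series(ta_max["S001"].to_numpy() - seasonal, index=ta_max.index)
        year = anom["2015"]
        assert year.idxmax() == pd.Timestamp("2015-07-17")

    def test_ar1_stationary_sd_recovered(self):
        """Sample sd of the AR(1) anomaly over ~2555 days within 10% of
        the configured sd."""
        cfg = SimConfig(n_sites=1, n_years=7, heat_waves=[], air_ar1_sd=2.0,
                        diurnal_range_sd=0.0)
        elev = pd.Series({"S001": 200.0})
        ta_max, _ = generate_climate(cfg, elev, np.random.default_rng(12))
        doy = ta_max.index.dayofyear.to_numpy()
        seasonal = cfg.air_mean + cfg.air_seasonal_amp * np.cos(
            2 * np.pi * (doy - 201) / 365.25
        )
        resid = ta_max["S001"].to_numpy() - seasonal
        # site noise (sd 0.5) adds in quadrature to the AR(1) sd
        expected = np.sqrt(2.0**2 + 0.5**2)
        assert resid.std() == pytest.approx(expected, rel=0.10)

    def test_night_never_warmer_than_day(self, small_study):
        for s in small_study.series.values():
            assert (s.data["ta_min"] <= s.data["ta_max"] + 1e-9).all()


class TestDischarge:
    def test_strictly_positive(self, small_study):
        for s in small_study.series.values():
            assert (s.data["q"] > 0).all()

    def test_no_quickflow_gives_bfi_one(self):
        cfg = small_sim_config()
        q, _, _ = generate_discharge(
            cfg, pd.Series({"S001": 1e-9}), np.random.default_rng(0)
        )
        assert compute_bfi(q["S001"]) == pytest.approx(1.0, abs=1e-6)

    def test_bfi_strictly_decreasing_in_quickflow_share(self):
        vals = []
        for share in (0.1, 0.3, 0.5, 0.7):
            cfg = small_sim_config()
            q, _, _ = generate_discharge(
                cfg, pd.Series({"S001": share}), np.random.default_rng(7)
            )
            vals.append(compute_bfi(q["S001"]))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_level_monotone_in_discharge(self, small_study):
        for s in small_study.series.values():
            df = s.data.sort_values("q")
            assert df["level"].is_monotonic_increasing


class TestMakeDataset:
    def test_determinism_identical_seeds(self):
        s1 = make_dataset(small_sim_config(), seed=5)
        s2 = make_dataset(small_sim_config(), seed=5)
        for sid in s1.series:
            pd.testing.assert_frame_equal(s1.series[sid].data, s2.series[sid].data)
        pd.testing.assert_frame_equal(s1.truth.params, s2.truth.params)
        assert np.array_equal(s1.dem.values, s2.dem.values)
        assert np.array_equal(s1.landcover.values, s2.landcover.values)

    def test_different_seeds_differ(self):
        s1 = make_dataset(small_sim_config(), seed=5)
        s2 = make_dataset(small_sim_config(), seed=6)
        sid = next(iter(s1.series))
        assert not np.allclose(s1.series[sid].data["tw_max"], s2.series[sid].data["tw_max"])

    def test_counts_and_finiteness(self, small_study):
        cfg = small_study.config
        assert len(small_study.sites) == cfg.n_sites
        assert len(small_study.truth.event_params) == cfg.n_sites * len(cfg.heat_waves)
        for s in small_study.series.values():
            assert np.isfinite(s.data["tw_max"]).all()

    def test_truth_sensitivities_nonnegative(self, small_study):
        assert (small_study.truth.params[["a", "b"]] >= 0).all().all()

    def test_dem_decreases_along_stem(self):
        """Terrain (surface model without canopy) falls monotonically
        along the channel; sampled off-line cell centers allow a small
        cross-slope wobble."""
        study = make_dataset(small_sim_config(tree_density_range=(0.0, 0.0)), seed=9)
        for r in study.network.reaches.values():
            if "stem" not in r.reach_id:
                continue
            step = max(1, len(r.vertices) // 8)
            z = [study.dem.value_at(x, y) for x, y in r.vertices[::step]]
            assert all(a >= b - 0.3 for a, b in zip(z, z[1:]))

    def test_landcover_uses_the_eight_codes(self, small_study):
        codes = set(np.unique(small_study.landcover.values).astype(int))
        assert codes <= set(range(1, 9))

    def test_noise_free_linear_link_gives_r2_one(self):
        """coef sd 0 and obs sd 0: the fitted summer parameters are an
        exact linear function of the measured standardized covariates, so
        the full OLS on any scale has R^2 = 1."""
        from streamtherm.config import PREDICTOR_ORDER, PipelineConfig
        from streamtherm.pipeline import run_pipeline

        truth = CoefficientTruth(coef_sd=0.0)
        for p, s in truth.slopes.items():
            truth.slopes[p] = {k: v / 2 for k, v in s.items()}
        cfg = PipelineConfig()
        cfg.sim = small_sim_config(n_sites=20, truth=truth, obs_sd=0.0)
        out = run_pipeline(cfg)
        assert out.study.truth.n_floored == 0
        tab = out.tables["CA"].dropna()
        X = sm.add_constant(tab[PREDICTOR_ORDER])
        for resp in ("a", "b", "c"):
            r2 = sm.OLS(tab[resp], X).fit().rsquared
            assert r2 == pytest.approx(1.0, abs=1e-6)


class TestShadeDial:
    def test_median_shade_nondecreasing_in_tree_density(self):
        """Raising riparian tree density (fixed seed) raises the median
        shade on the water surface."""
        from streamtherm.landscape import (
            build_scale_masks,
            hillshade_angle,
            shade_metric,
            solar_position,
            water_surface_mask,
        )

        medians = []
        for dens in (0.0, 0.4, 0.8):
            cfg = small_sim_config(tree_density_range=(dens, dens), n_sites=3)
            study = make_dataset(cfg, seed=3)
            sun = solar_position("2015-07-17", cfg.latitude_deg)
            vals = []
            for sid, (x, y) in study.network.sites.items():
                poly = study.catchments[sid]
                xmin, ymin, xmax, ymax = poly.bounds
                win = study.dem.window(xmin - 100, ymin - 100, xmax + 100, ymax + 100)
                up = study.network.upstream_reaches(study.network.nearest_reach(x, y))
                ms = build_scale_masks(poly, (x, y), study.network, win, up)
                wm = water_surface_mask(study.network, win, reach_ids=up)
                vals.append(shade_metric(hillshade_angle(win, sun), wm, ms.masks["CA"]))
            medians.append(np.mean(vals))
        assert medians[0] < medians[1] <= medians[2]

    def test_zero_density_equals_flat_water_incidence(self):
        from streamtherm.landscape import (
            build_scale_masks,
            hillshade_angle,
            shade_metric,
            solar_position,
            water_surface_mask,
        )

        cfg = small_sim_config(
            n_sites=2, tree_density_range=(0.0, 0.0),
            valley_cross_slope=0.0, valley_gradient=0.0,
        )
        study = make_dataset(cfg, seed=1)
        sun = solar_position("2015-07-17", cfg.latitude_deg)
        sid, (x, y) = next(iter(study.network.sites.items()))
        poly = study.catchments[sid]
        xmin, ymin, xmax, ymax = poly.bounds
        win = study.dem.window(xmin - 100, ymin - 100, xmax + 100, ymax + 100)
        up = study.network.upstream_reaches(study.network.nearest_reach(x, y))
        ms = build_scale_masks(poly, (x, y), study.network, win, up)
        wm = water_surface_mask(study.network, win, reach_ids=up)
        got = shade_metric(hillshade_angle(win, sun), wm, ms.masks["CA"])
        assert got == pytest.approx(90.0 - sun.elevation_deg, abs=1e-9)
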