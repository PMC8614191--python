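"""Landscape metrics: BFI, solar geometry, hillshade, masks, zonal stats."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from streamtherm.grids import RasterGrid
from streamtherm.landscape import (
    build_scale_masks,
    channel_slope,
    compute_bfi,
    hillshade_angle,
    landcover_proportions,
    network_sinuosity,
    shade_metric,
    solar_position,
    water_surface_mask,
)
from streamtherm.network import Reach, RiverNetwork


class TestBFI:
    def test_constant_flow_is_exactly_one(self):
        assert compute_bfi(np.ones(90) * 3.7) == 1.0

    def test_hand_worked_spike_series(self):
        """60 days of unit flow with a triangular spike [4,7,10,7,4] on
        days 30-34.  Every 5-day block still contains a unit-flow day, so
        all block minima are 1, the baseline is flat at 1 between the
        first and last block-minimum days (0 and 55), and
        BFI = 56 / (51 + 32) = 56/83, executed by hand."""
        q = np.ones(60)
        q[29:34] = [4.0, 7.0, 10.0, 7.0, 4.0]
        assert compute_bfi(q) == pytest.approx(56.0 / 83.0, abs=1e-12)

    def test_interpolated_baseline_hand_oracle(self):
        """15 days in three blocks with minima 2, 8, 4 at days 0, 5, 10.
        0.9*8 = 7.2 exceeds both neighbours so the middle block is not a
        turning point; the baseline interpolates 2 -> 4 over days 0..10
        (values 2, 2.2, ..., 4), none capped.  Hand sums: baseline 33,
        flow [2,3,3,3,3,8,9,9,9,9,4] = 62, so BFI = 33/62."""
        q = np.array([2, 3, 3, 3, 3, 8, 9, 9, 9, 9, 4, 5, 5, 5, 5], dtype=float)
        assert compute_bfi(q) == pytest.approx(33.0 / 62.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        q = rng.lognormal(0.5, 0.6, 200)
        assert compute_bfi(q) == pytest.approx(compute_bfi(5.3 * q), abs=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            compute_bfi(np.ones(12))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(15, 400))
    def test_bounded_between_zero_and_one(self, seed, n):
        q = np.random.default_rng(seed).lognormal(0.0, 1.0, n) + 1e-3
        assert 0.0 <= compute_bfi(q) <= 1.0


class TestSolarPosition:
    def test_equinox_elevation_at_lat_50(self):
        sun = solar_position("2015-03-21", 50.0)
        assert sun.elevation_deg == pytest.approx(40.0, abs=0.5)
        assert sun.declination_deg == pytest.approx(0.0, abs=0.5)

    def test_summer_solstice_elevation_at_lat_50(self):
        sun = solar_position("2015-06-21", 50.0)
        assert sun.elevation_deg == pytest.approx(63.4, abs=0.5)

    def test_noon_azimuth_is_south(self):
        assert solar_position("2015-07-01", 45.0).azimuth_deg == 180.0

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError, match="polar"):
            solar_position("2015-06-21", 70.0)


class TestHillshade:
    def flat(self, n=9, z=100.0, cell=10.0):
        return RasterGrid(np.full((n, n), z), 0.0, 0.0, cell)

    def sun_at(self, elevation):
        from streamtherm.landscape import SolarPosition

        return SolarPosition(pd.Timestamp("2015-07-01"), 50.0, 0.0, elevation, 180.0)

    def test_flat_dem_overhead_sun_no_shade(self):
        sh = hillshade_angle(self.flat(), self.sun_at(90.0), cast_shadows=False)
        assert np.allclose(sh.values, 0.0, atol=1e-9)

    def test_flat_dem_shade_is_complement_of_elevation(self):
        sh = hillshade_angle(self.flat(), self.sun_at(60.0))
        assert np.allclose(sh.values, 30.0, atol=1e-9)

    def test_slope_facing_sun_at_matching_elevation_has_zero_shade(self):
        """A 45-degree south-facing slope under a 45-degree sun: the
        surface normal is parallel to the sun direction (3-D vector
        oracle), so the incidence shade angle is zero."""
        cell = 10.0
        rows = np.arange(21, dtype=float)
        # row 0 is northernmost and highest: elevation falls southward
        z = (20.0 - rows)[:, None] * cell * np.ones((1, 21))
        dem = RasterGrid(z, 0, 0, cell)
        sh = hillshade_angle(dem, self.sun_at(45.0), cast_shadows=False)
        assert np.allclose(sh.values[1:-1, 1:-1], 0.0, atol=1e-6)

    def test_cast_shadow_behind_wall(self):
        """A tall ridge running east-west shadows the cells to its north
        when the sun is due south at moderate elevation."""
        z = np.full((15, 15), 0.0)
        z[8, :] = 30.0  # wall; rows 0-7 are north of it
        dem = RasterGrid(z, 0, 0, 10.0)
        sun = self.sun_at(45.0)
        shaded = hillshade_angle(dem, sun, cast_shadows=True)
        unshaded = hillshade_angle(dem, sun, cast_shadows=False)
        # 30 m wall, 45-degree sun: shadow reaches 3 cells north (rows 5-7)
        assert np.all(shaded.values[5:8, 2:-2] == 90.0)
        # row 6 is flat terrain (Horn stencil clear of the wall): only the
        # ray-march, not incidence, can shade it
        assert np.all(unshaded.values[6, 2:-2] < 90.0)
        assert np.all(shaded.values[4, 2:-2] < 90.0)  # beyond the shadow

    def test_tiny_dem_rejected(self):
        sun = solar_position("2015-06-21", 50.0)
        with pytest.raises(ValueError):
            hillshade_angle(RasterGrid(np.zeros((2, 2)), 0, 0, 10.0), sun)


def straight_net(da=10.0, length=2000.0, y=50.0):
    r = Reach("r0", np.array([[0.0, y], [length, y]]), da)
    return RiverNetwork({"r0": r}, {"S1": (length, y)})


class TestWaterMask:
    def test_all_small_reaches_empty_mask(self):
        net = straight_net(da=0.5)
        grid = RasterGrid(np.zeros((100, 100)), 0, 0, 1.0)
        assert water_surface_mask(net, grid).sum() == 0

    def test_corridor_width_matches_buffer(self):
        """2 m half-width corridor on 1 m cells selects ~4 m of width."""
        net = straight_net(da=10.0, length=100.0, y=50.0)
        grid = RasterGrid(np.zeros((100, 100)), 0, 0, 1.0)
        mask = water_surface_mask(net, grid)
        area = mask.sum() * 1.0  # m2 at 1 m cells
        assert area == pytest.approx(100.0 * 4.0, rel=0.1)

    def test_mapped_reach_wider_than_corridor(self):
        wide = water_surface_mask(
            straight_net(da=100.0, length=100.0), RasterGrid(np.zeros((100, 100)), 0, 0, 1.0)
        )
        narrow = water_surface_mask(
            straight_net(da=10.0, length=100.0), RasterGrid(np.zeros((100, 100)), 0, 0, 1.0)
        )
        assert wide.sum() > narrow.sum()


class TestShadeMetric:
    def test_uniform_value(self):
        g = RasterGrid(np.full((5, 5), 25.0), 0, 0, 10.0)
        mask = np.ones((5, 5), bool)
        assert shade_metric(g, mask, mask) == 25.0

    def test_median_of_three(self):
        g = RasterGrid(np.zeros((1, 5)), 0, 0, 10.0)
        g.values[0, :3] = [10.0, 20.0, 30.0]
        water = np.zeros((1, 5), bool)
        water[0, :3] = True
        assert shade_metric(g, water, np.ones((1, 5), bool)) == 20.0

    def test_invariant_to_cells_outside_water(self):
        g = RasterGrid(np.arange(25.0).reshape(5, 5), 0, 0, 10.0)
        water = np.zeros((5, 5), bool)
        water[2, :] = True
        small = water.copy()
        big = np.ones((5, 5), bool)
        assert shade_metric(g, water, small) == shade_metric(g, water, big)

    def test_empty_intersection_is_nan(self, caplog):
        g = RasterGrid(np.zeros((3, 3)), 0, 0, 10.0)
        with caplog.at_level("WARNING", logger="streamtherm.landscape"):
            out = shade_metric(g, np.zeros((3, 3), bool), np.ones((3, 3), bool))
        assert math.isnan(out)


class TestLandcover:
    def test_single_class_is_100_percent(self):
        g = RasterGrid(np.full((10, 10), 3.0), 0, 0, 10.0)
        props = landcover_proportions(g, np.ones((10, 10), bool))
        assert props["BROAD"] == 100.0
        assert sum(props.values()) == pytest.approx(100.0, abs=0.1)

    def test_checkerboard_half_half(self):
        z = np.indices((10, 10)).sum(axis=0) % 2 + 1.0  # codes 1 and 2
        props = landcover_proportions(RasterGrid(z, 0, 0, 10.0), np.ones((10, 10), bool))
        assert props["AGRI"] == 50.0 and props["ARTI"] == 50.0

    def test_unmapped_code_error_names_code(self):
        g = RasterGrid(np.full((4, 4), 13.0), 0, 0, 10.0)
        with pytest.raises(ValueError, match="13"):
            landcover_proportions(g, np.ones((4, 4), bool))

    def test_18_class_mapping_applied(self):
        g = RasterGrid(np.full((4, 4), 13.0), 0, 0, 10.0)
        props = landcover_proportions(g, np.ones((4, 4), bool), class_mapping={13: 6})
        assert props["NEEDLE"] == 100.0

    def test_nodata_cells_excluded(self):
        z = np.full((4, 4), 1.0)
        z[0, 0] = -9999.0
        props = landcover_proportions(RasterGrid(z, 0, 0, 10.0), np.ones((4, 4), bool))
        assert props["AGRI"] == 100.0


class TestSinuosity:
    def test_straight_reach(self):
        net = straight_net()
        fp = box(-10, 0, 3000, 100)
        assert network_sinuosity(net, ["r0"], fp) == pytest.approx(1.0)

    def test_semicircle_is_pi_over_two(self):
        theta = np.linspace(0, math.pi, 400)
        verts = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta)])
        net = RiverNetwork({"r": Reach("r", verts, 5.0)}, {})
        fp = box(-200, -200, 200, 200)
        assert network_sinuosity(net, ["r"], fp) == pytest.approx(math.pi / 2, rel=1e-4)

    def test_length_weighted_mean(self):
        """Reaches of lengths 1 and 3 with sinuosities 1 and 2 -> 1.75."""
        r1 = Reach("r1", np.array([[0.0, 0.0], [1.0, 0.0]]), 5.0)
        # length 3, chord 1.5 -> sinuosity 2: zig-zag
        h = math.sqrt(0.5625 - 0.140625)  # rise for each of 4 segments... use param form
        # build a 4-segment polyline of total length 3 with endpoints 1.5 apart
        seg = 0.75
        dx = 1.5 / 4
        dy = math.sqrt(seg**2 - dx**2)
        pts = [[2.0, 0.0]]
        for i in range(4):
            pts.append([2.0 + dx * (i + 1), dy * ((i + 1) % 2)])
        r2 = Reach("r2", np.array(pts), 5.0)
        assert r2.sinuosity() == pytest.approx(2.0, rel=1e-9)
        net = RiverNetwork({"r1": r1, "r2": r2}, {})
        fp = box(-10, -10, 10, 10)
        assert network_sinuosity(net, ["r1", "r2"], fp) == pytest.approx(1.75, rel=1e-9)

    def test_rigid_motion_invariance(self):
        theta = np.linspace(0, math.pi, 200)
        verts = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta)])
        ang = 0.7
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        moved = verts @ rot.T + np.array([1234.0, -567.0])
        s1 = Reach("a", verts, 5.0).sinuosity()
        s2 = Reach("b", moved, 5.0).sinuosity()
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_closed_loop_rejected(self):
        theta = np.linspace(0, 2 * math.pi, 100)
        verts = np.column_stack([np.cos(theta), np.sin(theta)])
        with pytest.raises(ValueError, match="loop"):
            Reach("c", verts, 5.0).sinuosity()


class TestChannelSlope:
    def ramp_dem(self, g=0.01, cell=10.0, n=500):
        xs = (np.arange(n) + 0.5) * cell
        z = np.tile((n * cell - xs) * g, (50, 1))
        return RasterGrid(z, 0, 0, cell)

    def test_forty_meter_drop_over_four_km(self):
        dem = self.ramp_dem(g=0.01)
        net = straight_net(da=10.0, length=4000.0, y=250.0)
        # site mid-channel: 2 km each side
        net.sites["S1"] = (2000.0, 250.0)
        slope = channel_slope(dem, net, (2000.0, 250.0), 4000.0)
        assert slope == pytest.approx(1.0, rel=0.02)

    def test_flat_dem_zero_slope(self):
        dem = RasterGrid(np.zeros((50, 500)), 0, 0, 10.0)
        net = straight_net(da=10.0, length=4000.0, y=250.0)
        assert channel_slope(dem, net, (2000.0, 250.0), 4000.0) == 0.0

    def test_constant_gradient_invariant_to_truncation(self, caplog):
        """On a uniform ramp the slope equals 100 g no matter how much
        channel is available."""
        dem = self.ramp_dem(g=0.004)
        net = straight_net(da=10.0, length=1000.0, y=250.0)
        with caplog.at_level("WARNING", logger="streamtherm.landscape"):
            s = channel_slope(dem, net, (500.0, 250.0), 4000.0)
        assert s == pytest.approx(0.4, rel=0.03)
        assert any("available" in r.message for r in caplog.records)

    def test_site_off_network_rejected(self):
        dem = self.ramp_dem()
        net = straight_net(da=10.0, length=1000.0, y=250.0)
        with pytest.raises(ValueError, match="network"):
            channel_slope(dem, net, (500.0, 5000.0), 4000.0)


class TestScaleMasks:
    def setup_case(self, W=4000.0, cell=20.0):
        """Square catchment of side W with the site at the middle of the
        east edge and a straight stem along the centerline."""
        catch = box(0, 0, W, W)
        stem = Reach("r0", np.array([[0.0, W / 2], [W, W / 2]]), 16.0)
        net = RiverNetwork({"r0": stem}, {"S1": (W, W / 2)})
        n = int(W / cell) + 20
        grid = RasterGrid(np.zeros((n, n)), -10 * cell, -10 * cell, cell)
        return catch, net, grid

    def test_invariants_and_pair_identity(self):
        catch, net, grid = self.setup_case()
        ms = build_scale_masks(catch, (4000.0, 2000.0), net, grid, ["r0"])
        ms.validate()  # containment + buff_k_ripa = ripa & buff_k

    def test_half_disc_area_for_edge_site(self):
        """1 km disc at the mid-edge site clipped by the square: the
        clipped area is the analytic half-disc pi r^2 / 2."""
        catch, net, grid = self.setup_case()
        ms = build_scale_masks(catch, (4000.0, 2000.0), net, grid, ["r0"], radii_m=(1000.0, 2000.0))
        cell_area = grid.cellsize**2
        got = ms.masks["buff_1"].sum() * cell_area
        expected = math.pi * 1000.0**2 / 2.0
        assert got == pytest.approx(expected, rel=0.02)

    def test_radius_exceeding_catchment_gives_ca(self):
        catch, net, grid = self.setup_case(W=1000.0)
        ms = build_scale_masks(
            catch, (1000.0, 500.0), net, grid, ["r0"], radii_m=(50000.0, 60000.0)
        )
        assert (ms.masks["buff_1"] == ms.masks["CA"]).all()
        assert (ms.masks["buff_2"] == ms.masks["CA"]).all()
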