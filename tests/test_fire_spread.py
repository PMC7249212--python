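"""Fire-spread unit and property tests: ROS components, perimeter stepping,
arrival fields, and the analytic circular-growth limit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firevac.fire import (
    FireError,
    FirePerimeter,
    RosParameters,
    dem_gradient,
    effective_ros,
    ignition_seed,
    outward_normals,
    ros_max,
    simulate,
    slope_effect,
    step_perimeter,
    wind_effect,
)
from firevac.fixtures import FixtureSpec, make_landscape
from firevac.raster import PointSet, Raster, WindField


class TestRosMax:
    def test_zero_humidity_is_table_value(self):
        p = RosParameters(ros_max_by_fuel={1: 100.0}, humidity_damping=1.0)
        assert ros_max(1, 0.0, p) == 100.0

    def test_zero_damping_ignores_humidity(self):
        p = RosParameters(ros_max_by_fuel={1: 100.0}, humidity_damping=0.0)
        assert ros_max(1, 0.9, p) == 100.0

    def test_exponential_damping_closed_form(self):
        # 100 * e^(-1 * 0.5)
        p = RosParameters(ros_max_by_fuel={1: 100.0}, humidity_damping=1.0)
        assert ros_max(1, 0.5, p) == pytest.approx(60.65306597126334)

    def test_unknown_fuel_class(self):
        p = RosParameters(ros_max_by_fuel={1: 100.0})
        with pytest.raises(FireError, match="unknown fuel class"):
            ros_max(2, 0.0, p)

    @given(humidity=st.floats(0.0, 1.0), damping=st.floats(0.0, 10.0))
    def test_nonnegative_and_bounded_by_table(self, humidity, damping):
        p = RosParameters(ros_max_by_fuel={1: 100.0}, humidity_damping=damping)
        v = ros_max(1, humidity, p)
        assert 0.0 <= v <= 100.0


class TestWindEffect:
    def setup_method(self):
        self.params = RosParameters(wind_saturation_speed=10000.0)

    def test_calm_wind_is_one(self):
        assert wind_effect(np.array([1.0, 0.0]), WindField(0.0, 123.0), self.params) == 1.0

    def test_downwind_at_saturation_is_one(self):
        # wind FROM north -> downwind is south; spread south
        w = WindField(10000.0, 0.0)
        assert wind_effect(np.array([0.0, -1.0]), w, self.params) == pytest.approx(1.0)

    def test_upwind_at_saturation_is_minimum(self):
        # 1 - 1*(1 - (-1))/2 = 0
        w = WindField(10000.0, 0.0)
        assert wind_effect(np.array([0.0, 1.0]), w, self.params) == pytest.approx(0.0)

    def test_crosswind_half_saturation(self):
        # u = 0.5, cos(theta) = 0 -> 1 - 0.5*0.5 = 0.75
        w = WindField(5000.0, 0.0)
        assert wind_effect(np.array([1.0, 0.0]), w, self.params) == pytest.approx(0.75)

    @given(speed=st.floats(0.0, 1e6), direction=st.floats(0.0, 360.0),
           angle=st.floats(0.0, 2 * math.pi))
    def test_always_in_unit_interval(self, speed, direction, angle):
        d = np.array([math.cos(angle), math.sin(angle)])
        v = wind_effect(d, WindField(speed, direction), self.params)
        assert 0.0 <= v <= 1.0


class TestSlopeEffect:
    def test_flat_terrain_is_one(self):
        p = RosParameters(slope_coefficient=1.0)
        assert slope_effect(np.array([1.0, 0.0]), np.array([0.0, 0.0]), p) == 1.0

    def test_zero_coefficient_is_one(self):
        p = RosParameters(slope_coefficient=0.0)
        assert slope_effect(np.array([1.0, 0.0]), np.array([-5.0, 0.0]), p) == 1.0

    def test_uphill_unpenalized(self):
        p = RosParameters(slope_coefficient=1.0)
        # gradient rising along spread direction
        assert slope_effect(np.array([1.0, 0.0]), np.array([1.0, 0.0]), p) == 1.0

    def test_45_degree_downhill_value(self):
        # downhill steepness 1 with coefficient 1: 1 - 1/(1+1) = 0.5
        p = RosParameters(slope_coefficient=1.0)
        v = slope_effect(np.array([1.0, 0.0]), np.array([-1.0, 0.0]), p)
        assert v == pytest.approx(0.5)

    @given(gx=st.floats(-10, 10), gy=st.floats(-10, 10),
           angle=st.floats(0.0, 2 * math.pi), coeff=st.floats(0.0, 10.0))
    def test_always_in_unit_interval_and_uphill_ge_downhill(self, gx, gy, angle, coeff):
        p = RosParameters(slope_coefficient=coeff)
        d = np.array([math.cos(angle), math.sin(angle)])
        g = np.array([gx, gy])
        up = slope_effect(d, g, p)
        down = slope_effect(-d, g, p)
        assert 0.0 <= up <= 1.0
        if float(np.dot(d, g)) > 0:  # d is the uphill direction
            assert up >= down


class TestEffectiveRos:
    @pytest.mark.parametrize("rmax,w,s,expected", [
        (100.0, 1.0, 1.0, 100.0),
        (100.0, 0.5, 0.5, 25.0),
        (100.0, 0.0, 0.9, 0.0),
    ])
    def test_product(self, rmax, w, s, expected):
        assert effective_ros(rmax, w, s) == expected

    def test_factor_outside_unit_interval_rejected(self):
        with pytest.raises(FireError):
            effective_ros(100.0, 1.2, 0.5)
        with pytest.raises(FireError):
            effective_ros(100.0, 0.5, -0.1)

    @given(rmax=st.floats(0, 1e5), w=st.floats(0, 1), s=st.floats(0, 1))
    def test_never_exceeds_ceiling(self, rmax, w, s):
        assert 0.0 <= effective_ros(rmax, w, s) <= rmax


class TestGeometryHelpers:
    def test_outward_normals_of_square_point_outward(self):
        ring = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        n = outward_normals(ring)
        center = ring.mean(axis=0)
        for v, nv in zip(ring, n):
            assert np.dot(nv, v - center) > 0
            assert np.linalg.norm(nv) == pytest.approx(1.0)

    def test_ignition_seed_is_regular_polygon(self):
        ring = ignition_seed(10.0, 20.0, radius=5.0, n_vertices=16)
        radii = np.linalg.norm(ring - [10.0, 20.0], axis=1)
        assert ring.shape == (16, 2)
        assert radii == pytest.approx(np.full(16, 5.0))

    def test_perimeter_needs_three_vertices(self):
        with pytest.raises(FireError):
            FirePerimeter(rings=[np.array([[0.0, 0.0], [1.0, 1.0]])])


class TestDemGradient:
    def test_ramp_gradient(self):
        spec = FixtureSpec(dem_style="ramp", ramp_gradient=0.1)
        dem, _, _, _ = make_landscape(spec)
        gx, gy = dem_gradient(dem)
        interior = slice(1, -1)
        assert gx[interior, interior] == pytest.approx(0.0, abs=1e-12)
        assert gy[interior, interior] == pytest.approx(0.1, abs=1e-9)


class TestStepPerimeter:
    def test_circle_expands_analytically(self, flat_landscape, no_damping_params):
        dem, fuel, hum, wind = flat_landscape
        ros = no_damping_params.ros_max_by_fuel[9]
        cx, cy = 501000.0, 4499000.0
        r0 = 100.0
        ring = ignition_seed(cx, cy, radius=r0, n_vertices=64)
        state = FirePerimeter(rings=[ring], timestamp=0.0)
        new = step_perimeter(state, dem, fuel, hum, wind, no_damping_params, dt=1.0)
        expected = r0 + ros / 60.0
        radii = np.linalg.norm(np.vstack(new.rings) - [cx, cy], axis=1)
        assert np.all(np.abs(radii - expected) <= 0.02 * expected)

    def test_zero_ros_leaves_perimeter_unchanged(self, flat_landscape):
        dem, fuel, hum, wind = flat_landscape
        params = RosParameters(ros_max_by_fuel={9: 0.0})
        ring = ignition_seed(501000.0, 4499000.0, radius=100.0, n_vertices=64)
        state = FirePerimeter(rings=[ring], timestamp=0.0)
        new = step_perimeter(state, dem, fuel, hum, wind, params, dt=5.0)
        assert new.area == pytest.approx(state.area, rel=1e-6)

    def test_disjoint_rings_merge_on_contact(self, flat_landscape, no_damping_params):
        dem, fuel, hum, wind = flat_landscape
        # two seeds 150 m apart; ROS 600 m/h covers 150 m in 15 min
        r1 = ignition_seed(500800.0, 4499000.0, radius=40.0)
        r2 = ignition_seed(500950.0, 4499000.0, radius=40.0)
        state = FirePerimeter(rings=[r1, r2], timestamp=0.0)
        for _ in range(15):
            state = step_perimeter(state, dem, fuel, hum, wind, no_damping_params, dt=1.0)
        merged = state.to_multipolygon()
        assert len(merged.geoms) == 1
        assert merged.geoms[0].exterior.is_simple
        # union area close to two-overlapping-circles analytic union
        import shapely
        from shapely.geometry import Point
        grown = 40.0 + no_damping_params.ros_max_by_fuel[9] * 15 / 60.0
        oracle = Point(500800.0, 4499000.0).buffer(grown, quad_segs=128).union(
            Point(500950.0, 4499000.0).buffer(grown, quad_segs=128))
        assert merged.area == pytest.approx(oracle.area, rel=0.03)

    def test_area_never_decreases(self, flat_landscape, no_damping_params):
        dem, fuel, hum, _ = flat_landscape
        wind = WindField(20000.0, 45.0)
        state = FirePerimeter(rings=[ignition_seed(501000.0, 4499000.0, 100.0)], timestamp=0.0)
        prev_area = state.area
        for _ in range(10):
            state = step_perimeter(state, dem, fuel, hum, wind, no_damping_params, dt=2.0)
            assert state.area >= prev_area - 1e-9
            prev_area = state.area

    def test_displacement_bound(self, flat_landscape, no_damping_params):
        dem, fuel, hum, wind = flat_landscape
        ring = ignition_seed(501000.0, 4499000.0, radius=100.0, n_vertices=64)
        state = FirePerimeter(rings=[ring], timestamp=0.0)
        dt = 3.0
        new = step_perimeter(state, dem, fuel, hum, wind, no_damping_params, dt=dt)
        max_step = max(no_damping_params.ros_max_by_fuel.values()) * dt / 60.0
        radii = np.linalg.norm(np.vstack(new.rings) - [501000.0, 4499000.0], axis=1)
        assert radii.max() <= 100.0 + max_step + 1e-6


class TestSimulate:
    def test_horizon_zero_returns_seed_only(self, flat_landscape, no_damping_params):
        dem, fuel, hum, wind = flat_landscape
        ign = PointSet(points=[("i", 501000.0, 4499000.0)], kind_tag="ignition")
        snaps, arrival = simulate(ign, dem, fuel, hum, wind, no_damping_params,
                                  dt=1.0, horizon=0.0)
        assert len(snaps) == 1
        assert snaps[0].timestamp == 0.0

    def test_ignition_outside_extent_rejected(self, flat_landscape, no_damping_params):
        dem, fuel, hum, wind = flat_landscape
        ign = PointSet(points=[("i", 0.0, 0.0)], kind_tag="ignition")
        with pytest.raises(FireError, match="outside raster extent"):
            simulate(ign, dem, fuel, hum, wind, no_damping_params, dt=1.0, horizon=5.0)

    def test_arrival_time_matches_distance_over_ros(self, flat_landscape, no_damping_params):
        dem, fuel, hum, wind = flat_landscape
        cx, cy = 501000.0, 4499000.0
        ign = PointSet(points=[("i", cx, cy)], kind_tag="ignition")
        ros = no_damping_params.ros_max_by_fuel[9]
        _, arrival = simulate(ign, dem, fuel, hum, wind, no_damping_params,
                              dt=1.0, horizon=40.0)
        X, Y = dem.cell_centers()
        d = np.hypot(X - cx, Y - cy)
        burned = arrival.values != arrival.nodata
        # sample cells well inside the burned disc (beyond the seed radius)
        sel = burned & (d > 3 * dem.cell_size)
        expected = 60.0 * (d[sel] - dem.cell_size) / ros  # seed starts at cell_size
        assert np.all(np.abs(arrival.values[sel] - expected) <= 1.5)

    def test_arrival_monotone_along_ray(self, flat_landscape, no_damping_params):
        dem, fuel, hum, wind = flat_landscape
        cx, cy = 501000.0, 4499000.0
        ign = PointSet(points=[("i", cx, cy)], kind_tag="ignition")
        _, arrival = simulate(ign, dem, fuel, hum, wind, no_damping_params,
                              dt=1.0, horizon=30.0)
        row0, col0 = arrival.index_of(cx, cy)
        ray = arrival.values[row0, col0:]
        ray = ray[ray != arrival.nodata]
        assert np.all(np.diff(ray) >= 0)

    def test_ignition_cell_arrival_zero(self, flat_landscape, no_damping_params):
        dem, fuel, hum, wind = flat_landscape
        cx, cy = 501000.0, 4499000.0
        ign = PointSet(points=[("i", cx, cy)], kind_tag="ignition")
        _, arrival = simulate(ign, dem, fuel, hum, wind, no_damping_params,
                              dt=1.0, horizon=2.0)
        assert arrival.values[arrival.index_of(cx, cy)] == 0.0

    def test_zero_ros_annihilation(self, flat_landscape):
        dem, fuel, hum, wind = flat_landscape
        params = RosParameters(ros_max_by_fuel={9: 0.0})
        cx, cy = 501000.0, 4499000.0
        ign = PointSet(points=[("i", cx, cy)], kind_tag="ignition")
        _, arrival = simulate(ign, dem, fuel, hum, wind, params, dt=1.0, horizon=20.0)
        burned = arrival.values != arrival.nodata
        X, Y = dem.cell_centers()
        d = np.hypot(X - cx, Y - cy)
        # only cells under the seed polygon (radius = one cell) ever burn
        assert np.all(d[burned] <= dem.cell_size + 1e-9)

    def test_snapshot_cadence(self, flat_landscape, no_damping_params):
        dem, fuel, hum, wind = flat_landscape
        ign = PointSet(points=[("i", 501000.0, 4499000.0)], kind_tag="ignition")
        snaps, _ = simulate(ign, dem, fuel, hum, wind, no_damping_params,
                            dt=1.0, horizon=20.0, snapshot_every=5.0)
        assert [s.timestamp for s in snaps] == [0.0, 5.0, 10.0, 15.0, 20.0]

    def test_determinism(self, flat_landscape, no_damping_params):
        dem, fuel, hum, wind = flat_landscape
        ign = PointSet(points=[("i", 501000.0, 4499000.0)], kind_tag="ignition")
        out1 = simulate(ign, dem, fuel, hum, wind, no_damping_params, dt=1.0, horizon=10.0)
        out2 = simulate(ign, dem, fuel, hum, wind, no_damping_params, dt=1.0, horizon=10.0)
        assert np.array_equal(out1[1].values, out2[1].values)
        for a, b in zip(out1[0], out2[0]):
            assert len(a.rings) == len(b.rings)
            for ra, rb in zip(a.rings, b.rings):
                assert np.array_equal(ra, rb)

    def test_downwind_spread_faster_than_upwind(self, no_damping_params):
        spec = FixtureSpec(dem_style="flat", fuel_style="uniform",
                           uniform_fuel_class=9, humidity=0.0)
        dem, fuel, hum, _ = make_landscape(spec)
        wind = WindField(30000.0, 270.0)  # from west -> downwind is east
        cx, cy = 501000.0, 4499000.0
        ign = PointSet(points=[("i", cx, cy)], kind_tag="ignition")
        snaps, _ = simulate(ign, dem, fuel, hum, wind, no_damping_params,
                            dt=1.0, horizon=30.0)
        geom = snaps[-1].to_multipolygon()
        xmin, _, xmax, _ = geom.bounds
        east_reach, west_reach = xmax - cx, cx - xmin
        assert east_reach > west_reach * 1.5
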