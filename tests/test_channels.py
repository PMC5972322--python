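"""Channel planning: geometry primitives, anchors, clearance, deviation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from shapely.geometry import Point

import cordfit as cf
from cordfit.channels import (
    Channel,
    ClearanceError,
    DeviceModel,
    point_to_ellipse_edge,
    segment_segment_distance,
)
from cordfit.contours import scale_cross_section


def _sampling_distance_oracle(p1, q1, p2, q2, n=400):
    """Grid scan plus local refinement of the segment-pair distance."""
    s = np.linspace(0, 1, n)
    a = p1 + np.outer(s, q1 - p1)
    b = p2 + np.outer(s, q2 - p2)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)

    def f(x):
        u = np.clip(x[0], 0, 1)
        v = np.clip(x[1], 0, 1)
        return float(((p1 + u * (q1 - p1)) - (p2 + v * (q2 - p2))) @
                     ((p1 + u * (q1 - p1)) - (p2 + v * (q2 - p2))))

    res = minimize(f, [s[i], s[j]], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-16})
    return math.sqrt(max(0.0, res.fun))


coords = st.floats(-10, 10)


@given(st.tuples(*[coords] * 12))
def test_segment_distance_matches_sampling_oracle(v):
    p1, q1 = np.array(v[0:3]), np.array(v[3:6])
    p2, q2 = np.array(v[6:9]), np.array(v[9:12])
    exact = segment_segment_distance(p1, q1, p2, q2)
    oracle = _sampling_distance_oracle(p1, q1, p2, q2)
    assert exact == pytest.approx(oracle, abs=1e-6)


def test_parallel_segments_closed_form():
    d = segment_segment_distance([0, 0, 0], [0, 0, 25], [3, 0, 0], [3, 0, 25])
    assert d == pytest.approx(3.0)


class TestPointToEllipse:
    def test_center_distance_is_semi_minor(self):
        assert point_to_ellipse_edge(0, 0, 10, 7) == pytest.approx(3.5)

    def test_boundary_points_are_zero(self):
        assert point_to_ellipse_edge(5, 0, 10, 7) == pytest.approx(0, abs=1e-9)
        assert point_to_ellipse_edge(0, -3.5, 10, 7) == pytest.approx(0, abs=1e-9)

    def test_circle_case(self):
        assert point_to_ellipse_edge(1.0, 1.0, 6, 6) == pytest.approx(3 - math.sqrt(2))

    def test_outside_is_negative(self):
        assert point_to_ellipse_edge(7, 0, 10, 7) == pytest.approx(-2.0)

    @given(st.floats(-6, 6), st.floats(-4, 4))
    def test_matches_dense_sampling(self, x, y):
        a, b = 4.7, 3.1
        theta = np.linspace(0, 2 * math.pi, 200_000)
        bound = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        d = np.min(np.hypot(bound[:, 0] - x, bound[:, 1] - y))
        signed = point_to_ellipse_edge(x, y, 2 * a, 2 * b)
        assert abs(signed) == pytest.approx(d, abs=1e-6)


@pytest.fixture(scope="module")
def planning_setup(table, thoracic_pop):
    catalog = cf.build_configured_catalog(table, population=thoracic_pop)
    model = cf.build_average_thoracic_model(table, seed=0, n_points=192)
    iface = catalog["normal 2"]
    cs = scale_cross_section(model["combined"], iface.transverse_mm, iface.ap_mm)
    layout = cf.ChannelLayoutConfig()
    anchors = cf.derive_anchor_set(cs, layout)
    return catalog, iface, cs, layout, anchors


class TestAnchorDerivation:
    def test_mirror_pairs_exact(self, planning_setup):
        _, _, _, _, anchors = planning_setup
        pts = anchors.all_points()
        for label, (x, y) in pts.items():
            side = "left" if label.endswith("left") else "right"
            other = label.replace(side, "left" if side == "right" else "right")
            assert pts[other] == (-x, y)

    def test_containment_predicates(self, planning_setup):
        _, _, cs, _, anchors = planning_setup
        outer, gray = cs.outer.polygon, cs.gray.polygon
        for pt in list(anchors.cranial_anchors.values()) + list(anchors.caudal_anchors.values()):
            assert outer.contains(Point(pt)) and not gray.contains(Point(pt))
        for pt in list(anchors.caudal_targets.values()) + list(anchors.cranial_targets.values()):
            assert gray.contains(Point(pt))

    def test_no_white_matter_along_sector_fails(self):
        # gray coincident with the outer boundary leaves no white matter anywhere
        from cordfit.contours import Contour, CrossSection

        phi = np.linspace(0, 2 * math.pi, 64, endpoint=False) + math.pi / 2
        ring = Contour(np.column_stack([4.0 * np.cos(phi), 4.0 * np.sin(phi)]))
        degenerate = CrossSection(outer=ring, gray=ring)
        with pytest.raises(ValueError, match="white matter"):
            cf.derive_anchor_set(degenerate, cf.ChannelLayoutConfig())


class TestPlanning:
    def test_default_layout_feasible(self, planning_setup):
        _, iface, _, layout, anchors = planning_setup
        device = cf.plan_channels(anchors, iface, 25.0, layout)
        report = cf.check_clearance(device, layout.wall_min_mm)
        assert report.passed
        assert report.min_wall_mm >= 0.4
        assert all(m >= 0.4 for m in report.boundary_margins_mm.values())

    def test_single_channel_always_feasible(self, planning_setup):
        _, iface, _, layout, _ = planning_setup
        ch = Channel("solo", "descending", (1.0, 1.0), (-1.0, -0.5), layout.channel_radius_mm)
        device = DeviceModel(iface, 25.0, (ch,))
        assert cf.check_clearance(device).passed

    def test_inflated_radii_fail_with_pair_reported(self, planning_setup):
        _, iface, _, _, anchors = planning_setup
        fat = cf.ChannelLayoutConfig(channel_radius_mm=1.4)
        with pytest.raises(ClearanceError) as err:
            cf.plan_channels(anchors, iface, 25.0, fat)
        assert len(err.value.report.violating_pairs) >= 1

    def test_parallel_channel_wall_exact(self, planning_setup):
        _, iface, _, _, _ = planning_setup
        c1 = Channel("a", "descending", (-1.5, 0.0), (-1.5, 0.0), 0.5)
        c2 = Channel("b", "descending", (1.5, 0.0), (1.5, 0.0), 0.4)
        report = cf.check_clearance(DeviceModel(iface, 25.0, (c1, c2)))
        assert report.min_wall_mm == pytest.approx(3.0 - 0.9)

    def test_center_channel_boundary_margin(self, planning_setup):
        _, iface, _, _, _ = planning_setup
        ch = Channel("mid", "descending", (0.0, 0.0), (0.0, 0.0), 0.5)
        report = cf.check_clearance(DeviceModel(iface, 25.0, (ch,)))
        assert report.boundary_margins_mm["mid"] == pytest.approx(iface.ap_mm / 2 - 0.5)

    def test_straight_channel_stays_inside_by_convexity(self, planning_setup):
        _, iface, _, layout, anchors = planning_setup
        device = cf.plan_channels(anchors, iface, 25.0, layout)
        for c in device.channels:
            p0, p1 = np.array(c.entry_xy), np.array(c.exit_xy)
            for t in np.linspace(0, 1, 21):
                x, y = p0 + t * (p1 - p0)
                assert point_to_ellipse_edge(x, y, iface.transverse_mm, iface.ap_mm) >= c.radius_mm


class TestDeviation:
    def test_zero_when_size_equals_device(self, planning_setup):
        catalog, iface, _, _, anchors = planning_setup
        _, devs = cf.channel_deviation(iface.transverse_mm, iface.ap_mm, catalog, anchors)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in devs.values())

    def test_zero_at_origin_anchor(self, planning_setup):
        catalog, _, _, _, anchors = planning_setup
        from cordfit.channels import AnchorSet
        origin = AnchorSet({"o": (0.0, 0.0)}, {}, {}, {}, ())
        _, devs = cf.channel_deviation(12.0, 9.0, catalog, origin)
        assert devs["o"] == 0.0

    @given(st.floats(4.0, 14.0), st.floats(3.0, 10.0))
    def test_bounded_by_half_euclid_error(self, t, ap):
        catalog = _CAT
        device_id = cf.assign_best_device(t, ap, catalog)
        iface = catalog[device_id]
        rec = cf.compute_fit_record(t, ap, iface)
        _, devs = cf.channel_deviation(t, ap, catalog, _ANCHORS, device_id=device_id)
        for v in devs.values():
            assert v <= rec["e_euclid_mm"] / 2 + 1e-9

    def test_monotone_along_ray(self, planning_setup):
        catalog, iface, _, _, anchors = planning_setup
        from cordfit.channels import AnchorSet
        rays = AnchorSet({f"r{k}": (0.3 * k, 0.2 * k) for k in range(5)}, {}, {}, {}, ())
        _, devs = cf.channel_deviation(10.0, 7.5, catalog, rays, device_id=iface.id)
        vals = [devs[f"r{k}"] for k in range(5)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


# module-level fixtures for hypothesis tests (no fixture injection)
_TABLE = cf.load_morphometry_table()
_POP = cf.simulate_population(
    _TABLE, cf.SimulationConfig(n_per_segment=40, seed=5, segments=cf.ANALYSIS_SEGMENTS))
_CAT = cf.build_configured_catalog(_TABLE, population=_POP)
_MODEL = cf.build_average_thoracic_model(_TABLE, seed=0, n_points=128)
_IFACE = _CAT["normal 2"]
_ANCHORS = cf.derive_anchor_set(
    scale_cross_section(_MODEL["combined"], _IFACE.transverse_mm, _IFACE.ap_mm))
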