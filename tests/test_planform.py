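"""Wing outline geometry: leading edge, trailing-edge Bezier, areas."""

import numpy as np
import pytest

from pterowing import pipeline
from pterowing.growth import build_growth_series
from pterowing.planform import (
    GeometryError,
    PostureSpec,
    bezier_polyline,
    build_hindlimb,
    build_leading_edge,
    build_planform,
    line_intersection,
    planform_area,
    planform_svg,
    trailing_edge,
)
from pterowing.postures import get_posture, load_postures
from pterowing.synthetic import preset_library, population_ac

from test_growth import make_seed

FLAT = PostureSpec("flat", {e: 0.0 for e in
                            ("humerus", "ulna_radius", "mcIV", "wp1",
                             "wp2", "wp3", "wp4")})


class TestLeadingEdge:
    def test_zero_angles_run_straight_lateral(self):
        lengths = {e: 100.0 for e in FLAT.sweep}
        joints = build_leading_edge(lengths, FLAT, shoulder=(10.0, 5.0))
        assert joints.shape == (8, 2)
        assert joints[-1] == pytest.approx([710.0, 5.0])

    def test_near_ninety_degrees_sweeps_posterior(self):
        post = PostureSpec("steep", {e: 89.9 for e in FLAT.sweep})
        lengths = {e: 100.0 for e in FLAT.sweep}
        joints = build_leading_edge(lengths, post, shoulder=(0.0, 0.0))
        assert joints[-1][0] == pytest.approx(0.0, abs=2.0)
        assert joints[-1][1] == pytest.approx(-700.0, abs=0.01)

    def test_thirty_degree_segment_hand_trigonometry(self):
        post = PostureSpec("one", dict(FLAT.sweep, humerus=30.0))
        lengths = {e: 100.0 for e in FLAT.sweep}
        joints = build_leading_edge(lengths, post, shoulder=(0.0, 0.0))
        assert joints[1] == pytest.approx([86.60254, -50.0], abs=1e-5)

    def test_combined_distal_phalanges(self):
        lengths = {e: 100.0 for e in FLAT.sweep}
        joints = build_leading_edge(lengths, FLAT, (0.0, 0.0), combine_wp34=True)
        assert joints.shape == (7, 2)
        assert joints[-1] == pytest.approx([700.0, 0.0])


class TestHindlimb:
    def test_forty_five_degree_decomposition(self):
        knee, ankle = build_hindlimb(100.0, 100.0, hip=(50.0, 0.0))
        r = 100.0 / np.sqrt(2.0)
        assert knee == pytest.approx([50.0 + r, -r])
        assert ankle == pytest.approx([50.0 + r, -r - 100.0])

    def test_zero_tibia_degenerate(self):
        knee, ankle = build_hindlimb(80.0, 0.0, hip=(0.0, 0.0))
        assert np.allclose(knee, ankle)

    def test_linearity_under_doubling(self):
        hip = np.array([30.0, -10.0])
        _, a1 = build_hindlimb(70.0, 90.0, hip)
        _, a2 = build_hindlimb(140.0, 180.0, hip)
        assert np.allclose(a2 - hip, 2.0 * (a1 - hip))


class TestTrailingEdge:
    def test_intersection_matches_independent_solve(self):
        # ankle (0,0), tibia (0,-1); wingtip (10,10), phalanx (1,0): the
        # construction lines are at 60 and 30 degrees above +x; solve the
        # 2x2 system independently
        edge = trailing_edge((0.0, 0.0), (0.0, -1.0), (10.0, 10.0), (1.0, 0.0))
        dA = np.array([np.cos(np.radians(60)), np.sin(np.radians(60))])
        dB = np.array([np.cos(np.radians(30)), np.sin(np.radians(30))])
        t = np.linalg.solve(np.column_stack([dA, -dB]),
                            np.array([10.0, 10.0]))
        expected = t[0] * dA
        assert edge.P1 == pytest.approx(tuple(expected), abs=1e-9)
        assert 0.0 <= edge.P1[0] <= 10.0

    def test_mirror_equivariance(self):
        e = trailing_edge((5.0, -40.0), (0.0, -1.0), (300.0, -30.0), (0.6, -0.8))
        m = trailing_edge((-5.0, -40.0), (0.0, -1.0), (-300.0, -30.0), (-0.6, -0.8))
        assert m.P1[0] == pytest.approx(-e.P1[0], rel=1e-9)
        assert m.P1[1] == pytest.approx(e.P1[1], rel=1e-9)

    def test_p2_equals_p3(self):
        edge = trailing_edge((0.0, 0.0), (0.0, -1.0), (100.0, -20.0), (0.7, -0.7))
        assert edge.P2 == edge.P3

    def test_parallel_lines_rejected(self):
        with pytest.raises(GeometryError, match="parallel"):
            line_intersection(np.zeros(2), np.array([1.0, 0.0]),
                              np.array([0.0, 1.0]), np.array([-2.0, 0.0]))


class TestBezier:
    def test_endpoint_interpolation(self):
        edge = trailing_edge((0.0, 0.0), (0.0, -1.0), (100.0, -20.0), (0.7, -0.7))
        pts = bezier_polyline(edge, 17)
        assert pts[0] == pytest.approx(edge.P0)
        assert pts[-1] == pytest.approx(edge.P3)

    def test_all_control_points_equal(self):
        from pterowing.planform import BezierTrailingEdge
        p = (3.0, -4.0)
        pts = bezier_polyline(BezierTrailingEdge(p, p, p, p), 9)
        assert np.allclose(pts, p)

    def test_collinear_control_points_stay_on_line(self):
        from pterowing.planform import BezierTrailingEdge
        edge = BezierTrailingEdge((0.0, 0.0), (1.0, 2.0), (3.0, 6.0), (3.0, 6.0))
        pts = bezier_polyline(edge, 101)
        residual = np.abs(pts[:, 1] - 2.0 * pts[:, 0])
        assert np.max(residual) < 1e-9


class TestArea:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert planform_area(sq) == pytest.approx(1.0)

    def test_triangle_shoelace_by_hand(self):
        tri = np.array([[0, 0], [4, 0], [0, 3]], float)
        assert planform_area(tri) == pytest.approx(6.0)

    def test_self_intersecting_rejected(self):
        bow = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], float)
        with pytest.raises(GeometryError, match="self-intersect"):
            planform_area(bow)

    def test_rigid_motion_invariance(self, rng):
        poly = np.array([[0, 0], [5, 1], [6, 4], [2, 6], [-1, 3]], float)
        theta = 0.77
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = poly @ R.T + np.array([12.3, -4.5])
        assert planform_area(moved) == pytest.approx(planform_area(poly), rel=1e-12)


def _series(taxon, presets):
    cfg = presets[taxon]
    return pipeline.growth_series_for(
        taxon, population_ac(cfg.b), pipeline.RunConfig()
    )


class TestBuildPlanform:
    def test_bezier_discretisation_converged(self, presets):
        series = _series("Rhamphorhynchus", presets)
        post = get_posture("Rhamphorhynchus")
        a1 = build_planform(series, post, 1.0, n_bezier=1024).wing_area_m2
        a2 = build_planform(series, post, 1.0, n_bezier=2048).wing_area_m2
        assert abs(a1 - a2) / a2 < 1e-4

    def test_area_agrees_with_polygon_library(self, presets):
        from shapely.geometry import Polygon

        for taxon in presets:
            series = _series(taxon, presets)
            post = get_posture(taxon)
            pf = build_planform(series, post, 2.0,
                                combine_wp34=(taxon == "anurognathids"))
            shapely_area = Polygon(pf.outline).area * 1e-6
            assert abs(pf.single_wing_area_m2 - shapely_area) / shapely_area < 5e-4

    def test_doubling_lengths_quadruples_area_fixes_ar(self):
        ac = {d: 1.0 for d in make_seed().measurements}
        ac["wingspan"] = 1.0
        s1 = build_growth_series(make_seed(1.0), ac)
        s2 = build_growth_series(make_seed(2.0), ac)
        post = get_posture("Rhamphorhynchus")
        Z1 = s1.seed_wingspan_m
        p1 = build_planform(s1, post, Z1)
        p2 = build_planform(s2, post, 2 * Z1)
        assert p2.wing_area_m2 == pytest.approx(4 * p1.wing_area_m2, rel=1e-9)
        assert p2.aspect_ratio == pytest.approx(p1.aspect_ratio, rel=1e-9)

    def test_isometric_series_constant_aspect_ratio(self):
        ac = {d: 1.0 for d in make_seed().measurements}
        ac["wingspan"] = 1.0
        series = build_growth_series(make_seed(), ac)
        post = get_posture("neutral", "neutral")
        ars = [build_planform(series, post, float(Z)).aspect_ratio
               for Z in series.grid_m[::10]]
        assert np.allclose(ars, ars[0], rtol=1e-9)

    def test_ontogenetic_aspect_ratio_directions(self, presets):
        # published trend directions: increase in Pteranodon, decrease in
        # Sinopterus and Pterodactylus, under both postures
        for taxon, sign in (("Pteranodon", 1), ("Sinopterus", -1),
                            ("Pterodactylus", -1)):
            series = _series(taxon, presets)
            for kind in ("taxon_specific", "neutral"):
                post = get_posture(taxon, kind)
                ar0 = build_planform(series, post, 0.3).aspect_ratio
                ar1 = build_planform(series, post, 7.0).aspect_ratio
                assert sign * (ar1 - ar0) > 0, (taxon, kind)

    def test_svg_export_is_wellformed_xml(self, presets):
        import xml.etree.ElementTree as ET

        series = _series("Pteranodon", presets)
        pf = build_planform(series, get_posture("Pteranodon"), 5.0)
        root = ET.fromstring(planform_svg(pf))
        assert root.tag.endswith("svg")
        assert len(root.findall(".//{http://www.w3.org/2000/svg}path")) == 2


def test_posture_presets_complete():
    presets = load_postures()
    assert "neutral" in presets
    for name, spec in presets.items():
        assert spec.femur_angle == 45.0
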