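"""Boundary construction, measurement, resampling, meshing, and cuts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphogrow.geometry import (
    BoundaryCurve,
    GeometryError,
    apply_cut,
    make_elliptical_cluster,
    make_parabolic_cluster,
    mesh_interior,
    outward_normals,
    polygon_area,
    resample_boundary,
    symmetrize_curve,
)


def square(n_per_side=20):
    s = np.linspace(0.0, 1.0, n_per_side, endpoint=False)
    pts = np.concatenate([
        np.column_stack([s, np.zeros_like(s)]),
        np.column_stack([np.ones_like(s), s]),
        np.column_stack([1.0 - s, np.ones_like(s)]),
        np.column_stack([np.zeros_like(s), 1.0 - s]),
    ])
    return BoundaryCurve(pts)


class TestConstructors:
    @pytest.mark.parametrize("x0,y0,exact", [
        (1.5, 1.0, 1.0),        # (2/3)·x0·y0 for the standard initial cluster
        (1.0, 1.0, 2.0 / 3.0),
        (2.0, 0.5, 2.0 / 3.0),
    ])
    def test_parabola_area_matches_closed_form(self, x0, y0, exact):
        c = make_parabolic_cluster(x0, y0, 0.02)
        assert polygon_area(c) == pytest.approx(exact, rel=1e-2)

    def test_parabola_tip_and_width(self):
        c = make_parabolic_cluster(1.5, 1.0, 0.05)
        tip = c.points[np.argmax(c.points[:, 0])]
        assert tip == pytest.approx([1.5, 0.0], abs=0.05)
        assert c.points[:, 1].max() == pytest.approx(0.5, abs=0.03)
        assert c.points[:, 1].min() == pytest.approx(-0.5, abs=0.03)
        # flat back at x̃ = 0 (spline resampling rounds the corners by O(h/10))
        assert c.points[:, 0].min() == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("x0,y0,exact", [
        (2.0, 2.0, np.pi),
        (1.5, 1.0, np.pi * 0.75 * 0.5),
        (1.6, 0.4, np.pi * 0.8 * 0.2),
    ])
    def test_ellipse_area(self, x0, y0, exact):
        c = make_elliptical_cluster(x0, y0, 0.02)
        assert polygon_area(c) == pytest.approx(exact, rel=1e-2)

    @pytest.mark.parametrize("maker", [make_parabolic_cluster, make_elliptical_cluster])
    def test_rejects_nonpositive_dimensions(self, maker):
        with pytest.raises(GeometryError):
            maker(-1.0, 1.0, 0.05)
        with pytest.raises(GeometryError):
            maker(1.0, 0.0, 0.05)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(x0=st.floats(0.5, 3.0), y0=st.floats(0.3, 2.0))
    def test_constructors_symmetric_about_axis(self, x0, y0):
        for maker in (make_parabolic_cluster, make_elliptical_cluster):
            c = maker(x0, y0, 0.05)
            mirrored = symmetrize_curve(c)
            assert np.max(np.abs(mirrored.points - c.points)) < 0.05 / 10


class TestMeasures:
    def test_unit_square_area(self):
        assert polygon_area(square()) == pytest.approx(1.0)

    def test_circle_area_fine_sampling(self, unit_disk):
        assert polygon_area(unit_disk) == pytest.approx(np.pi, rel=1e-3)

    def test_reversed_orientation_is_negative(self):
        c = BoundaryCurve(square().points[::-1])
        assert polygon_area(c) < 0

    def test_self_intersection_rejected(self):
        bowtie = BoundaryCurve(np.array([[0, 0], [1, 1], [1, 0], [0, 1.0]]))
        with pytest.raises(GeometryError):
            polygon_area(bowtie)

    def test_circle_normals_are_radial(self, unit_disk):
        n = outward_normals(unit_disk)
        radial = unit_disk.points / np.hypot(*unit_disk.points.T)[:, None]
        assert np.max(np.hypot(*(n - radial).T)) < 5e-3

    def test_parabola_tip_normal_points_forward(self):
        c = make_parabolic_cluster(1.5, 1.0, 0.05)
        i = np.argmax(c.points[:, 0])
        n = outward_normals(c)[i]
        assert n[0] > 0.99

    def test_square_edge_normals_axis_aligned(self):
        n = outward_normals(square())
        mid_bottom = 10  # midpoint of the bottom edge
        assert n[mid_bottom] == pytest.approx([0.0, -1.0], abs=1e-9)


class TestResampling:
    def test_spacing_uniform_after_resampling_clustered_points(self):
        th = np.concatenate([np.linspace(0, np.pi, 150, endpoint=False),
                             np.linspace(np.pi, 2 * np.pi, 15, endpoint=False)])
        c = BoundaryCurve(np.column_stack([np.cos(th), np.sin(th)]))
        r = resample_boundary(c, 0.05)
        seg = r.segment_lengths()
        assert np.std(seg) / np.mean(seg) < 0.1

    def test_idempotent(self, unit_disk):
        twice = resample_boundary(unit_disk, 0.05)
        assert np.max(np.hypot(*(twice.points - unit_disk.points).T)) < 0.05 / 10

    def test_arc_length_preserved(self, parabola):
        r = resample_boundary(parabola, 0.03)
        assert r.arc_length() == pytest.approx(parabola.arc_length(), rel=1e-2)

    def test_h_too_large_rejected(self):
        c = make_elliptical_cluster(0.4, 0.4, 0.02)
        with pytest.raises(GeometryError):
            resample_boundary(c, 5.0)


class TestInteriorMesh:
    def test_unit_square_weights(self):
        m = mesh_interior(square(), 0.1)
        assert m.weights.sum() == pytest.approx(1.0, abs=0.01)
        assert np.all(m.weights > 0)

    def test_weights_match_polygon_area(self, parabola):
        m = mesh_interior(parabola, 0.06)
        assert m.weights.sum() == pytest.approx(polygon_area(parabola), rel=1e-3)

    def test_refinement_reduces_area_error(self, unit_disk):
        # area error vs the polygon is tiny at any h; check it does not grow
        errs = []
        for hm in (0.1, 0.05):
            m = mesh_interior(unit_disk, hm)
            errs.append(abs(m.weights.sum() - polygon_area(unit_disk)))
        assert errs[1] <= errs[0] + 1e-12

    def test_all_nodes_inside(self, parabola):
        import shapely
        from shapely.geometry import Polygon

        m = mesh_interior(parabola, 0.06)
        poly = Polygon(parabola.points).buffer(1e-9)
        assert np.all(shapely.contains_xy(poly, m.nodes[:, 0], m.nodes[:, 1]))


class TestCuts:
    def _rod(self):
        # capsule-ish rod: rectangle with a rounded tip, bulk at the left
        th = np.linspace(-np.pi / 2, np.pi / 2, 40)
        cap = np.column_stack([2.0 + 0.3 * np.cos(th), 0.3 * np.sin(th)])
        top = np.column_stack([np.linspace(2.0, 0.0, 40), np.full(40, 0.3)])
        left = np.column_stack([np.zeros(10), np.linspace(0.3, -0.3, 12)[1:-1]])
        bot = np.column_stack([np.linspace(0.0, 2.0, 40), np.full(40, -0.3)])
        return resample_boundary(BoundaryCurve(np.vstack([bot, cap, top, left])), 0.05)

    def test_straight_cut_gives_flat_end(self):
        rod = self._rod()
        cut = apply_cut(rod, {"kind": "straight", "xc": 1.5}, 0.05)
        assert cut.points[:, 0].max() == pytest.approx(1.5, abs=0.06)
        # flat face: many points at x ≈ xc spanning the rod width
        face = cut.points[cut.points[:, 0] > 1.45]
        assert face[:, 1].max() - face[:, 1].min() > 0.5
        assert polygon_area(cut) < polygon_area(rod)

    def test_elliptical_cut_gives_convex_cap(self):
        rod = self._rod()
        cut = apply_cut(rod, {"kind": "elliptical", "center": (1.5, 0.0),
                              "semi_axes": (0.25, 0.3)}, 0.05)
        assert 1.5 < cut.points[:, 0].max() < 1.8
        # cap is smooth: no curvature spikes beyond the ellipse's own
        assert cut.is_simple()

    def test_cut_beyond_tip_errors(self):
        rod = self._rod()
        with pytest.raises(GeometryError):
            apply_cut(rod, {"kind": "straight", "xc": 5.0}, 0.05)

    def test_unknown_cut_kind_errors(self):
        with pytest.raises(GeometryError):
            apply_cut(self._rod(), {"kind": "diagonal"}, 0.05)


def test_symmetrize_damps_asymmetry(parabola):
    pts = parabola.points.copy()
    pts[:, 1] += 0.02 * np.sin(3 * pts[:, 0])  # antisymmetric-ish wobble
    perturbed = BoundaryCurve(pts)
    fixed = symmetrize_curve(perturbed)
    # the symmetrized curve is closer to its own mirror than the perturbed one
    resid_fixed = np.max(np.hypot(*(symmetrize_curve(fixed).points - fixed.points).T))
    resid_pert = np.max(np.hypot(*(symmetrize_curve(perturbed).points - perturbed.points).T))
    assert resid_fixed < 0.5 * resid_pert
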