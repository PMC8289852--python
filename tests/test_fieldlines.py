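"""Field evaluation, line tracing, and the stray/collapsed filters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString

import tubeunroll as tu

from conftest import CENTER, circle_points, ellipse_points, make_section


def radial_direction(point, center=CENTER):
    v = np.asarray(point, float) - np.asarray(center, float)
    return v / np.linalg.norm(v)


class TestInwardNormal:
    def test_circle_normal_points_into_the_wall(self, concentric_section):
        # the first-step normal at an inner point heads into the annulus,
        # i.e. radially outward, away from the lumen
        i = 0
        p = concentric_section.inner.points[i]
        n = tu.inward_normal(concentric_section, i, delta=2.0)
        expected = radial_direction(p)
        angle = np.arccos(np.clip(np.dot(n, expected), -1, 1))
        assert angle <= 2 * np.pi / concentric_section.n_points

    def test_square_annulus_edge_midpoint(self):
        def square(half):
            c = np.array(CENTER)
            corners = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])
            return c + corners

        section = make_section(square(10.0), square(30.0), n_points=40)
        # find the inner point nearest the middle of the right edge
        target = np.array([CENTER[0] + 10.0, CENTER[1]])
        i = int(np.argmin(np.linalg.norm(section.inner.points - target, axis=1)))
        n = tu.inward_normal(section, i, delta=2.0)
        assert np.allclose(n, [1.0, 0.0], atol=0.05)

    def test_star_shaped_first_step_lands_inside(self):
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        r_in = 20 + 4 * np.cos(5 * th)
        r_out = 45 + 6 * np.cos(3 * th + 1.0)
        inner = np.column_stack([CENTER[0] + r_in * np.cos(th), CENTER[1] + r_in * np.sin(th)])
        outer = np.column_stack([CENTER[0] + r_out * np.cos(th), CENTER[1] + r_out * np.sin(th)])
        section = make_section(inner, outer, n_points=120)
        delta = 2.0
        for i in range(section.n_points):
            n = tu.inward_normal(section, i, delta)
            assert n is not None
            assert tu.annulus_contains(section.inner.points[i] + delta * n, section)


class TestWindowIndices:
    @pytest.mark.parametrize("i, w, n, expected", [
        (0, 2, 10, [8, 9, 0, 1, 2]),
        (9, 2, 10, [7, 8, 9, 0, 1]),
        (5, 1, 10, [4, 5, 6]),
    ])
    def test_cyclic_windows(self, i, w, n, expected):
        assert tu.window_indices(i, w, n).tolist() == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_size_and_membership(self, data):
        n = data.draw(st.integers(min_value=3, max_value=300))
        w = data.draw(st.integers(min_value=1, max_value=(n - 1) // 2))
        i = data.draw(st.integers(min_value=0, max_value=n - 1))
        J = tu.window_indices(i, w, n)
        assert len(J) == 2 * w + 1
        assert len(set(J.tolist())) == 2 * w + 1
        assert i in J


class TestElectricField:
    def test_two_charge_direction(self, concentric_section):
        # field points from the positive (inner) toward the negative
        # (outer) charge, i.e. outward along +x between the two
        params = tu.FieldLineParams(n_points=200, window=15, delta=2, rigidity=1,
                                    k_max=75, v_min=1)
        p = np.array([CENTER[0] + 30.0, CENTER[1] + 0.1])
        i = int(np.argmin(np.abs(tu.geometry.azimuth(
            concentric_section.inner.points, CENTER))))
        E = tu.electric_field(p, concentric_section, i, params)
        assert E[0] > 0

    def test_full_window_field_is_radial(self, concentric_section):
        params = tu.FieldLineParams(n_points=200, window=99, delta=2, rigidity=1,
                                    k_max=75, v_min=1)
        for i in (0, 37, 123):
            p0 = concentric_section.inner.points[i]
            for t in (0.2, 0.5, 0.8):
                p = np.array(CENTER) + (1 + t) * (p0 - CENTER)
                E = tu.electric_field(p, concentric_section, i, params)
                E = E / np.linalg.norm(E)
                angle = np.degrees(np.arccos(np.clip(np.dot(E, radial_direction(p)), -1, 1)))
                assert angle < 1.0

    def test_linear_in_rigidity(self, concentric_section):
        mk = lambda rig: tu.FieldLineParams(n_points=200, window=15, delta=2,  # noqa: E731
                                            rigidity=rig, k_max=75, v_min=1)
        p = np.array([CENTER[0] + 27.0, CENTER[1] + 3.0])
        e1 = tu.electric_field(p, concentric_section, 0, mk(1.0))
        e2 = tu.electric_field(p, concentric_section, 0, mk(2.0))
        # E(rigidity) = E_inner + rigidity * E_outer_unit => linearity
        e_outer = e2 - e1
        e_inner = e1 - e_outer
        assert np.allclose(e_inner + 2 * e_outer, e2, rtol=0, atol=1e-12)

    def test_singularity_guard(self, concentric_section):
        params = tu.FieldLineParams(n_points=200, window=15, delta=2, rigidity=1,
                                    k_max=75, v_min=1)
        with pytest.raises(tu.SingularityError):
            tu.electric_field(concentric_section.inner.points[0], concentric_section, 0, params)


class TestTraceFieldLine:
    def test_concentric_complete_with_analytic_thickness(self, concentric_lines):
        assert len(concentric_lines) == 200
        for ln in concentric_lines:
            assert ln.status == tu.COMPLETE
            assert abs(ln.length - 20.0) < 0.5

    def test_kmax_too_small_gives_stray(self, concentric_section):
        params = tu.FieldLineParams(n_points=200, window=15, delta=2, rigidity=1,
                                    k_max=3, v_min=1)
        ln = tu.trace_field_line(concentric_section, 0, params)
        assert ln.status == tu.STRAY  # 3 steps of 2 px cannot cross 20 px

    def test_variance_filter_collapses_stalled_lines(self, concentric_section):
        # a huge v_min collapses even genuinely complete lines: the filter
        # is a pure variance threshold applied after tracing
        params = tu.FieldLineParams(n_points=200, window=15, delta=2, rigidity=1,
                                    k_max=75, v_min=1e6)
        ln = tu.trace_field_line(concentric_section, 0, params)
        assert ln.status == tu.COLLAPSED
        assert ln.length is None

    def test_variance_bounded_by_scatter_radius(self, concentric_lines):
        # all points within a disc of radius r about the centroid => V <= r^2 * (K+1)/K
        for ln in concentric_lines[:10]:
            centroid = ln.points.mean(axis=0)
            r = np.linalg.norm(ln.points - centroid, axis=1).max()
            k = len(ln.points) - 1
            assert ln.variance <= r * r * (k + 1) / k + 1e-9

    def test_final_point_clipped_onto_outer_boundary(self, concentric_lines):
        for ln in concentric_lines[::25]:
            r_end = np.linalg.norm(ln.points[-1] - CENTER)
            assert abs(r_end - 40.0) < 0.05

    def test_unclipped_length_is_step_quantised(self, concentric_section):
        params = tu.FieldLineParams(n_points=200, window=15, delta=2, rigidity=1,
                                    k_max=75, v_min=1)
        ln = tu.trace_field_line(concentric_section, 0, params, clip_final=False)
        assert ln.status == tu.COMPLETE
        assert abs(ln.length - ln.n_steps * 2.0) < 1e-9


class TestTraceAll:
    def test_all_lines_survive_on_analytic_annulus(self, concentric_lines):
        assert [ln.index for ln in concentric_lines] == list(range(200))

    def test_too_few_complete_lines_is_meshing_failure(self, concentric_section):
        params = tu.FieldLineParams(n_points=200, window=15, delta=2, rigidity=1,
                                    k_max=2, v_min=0)
        with pytest.raises(tu.MeshingFailure):
            tu.trace_all(concentric_section, params)

    def test_indices_strictly_increasing_subset(self):
        section = make_section(ellipse_points(18, 12, CENTER), ellipse_points(42, 30, CENTER),
                               n_points=64)
        params = tu.FieldLineParams(n_points=64, window=8, delta=1.5, rigidity=1,
                                    k_max=75, v_min=1)
        lines = tu.trace_all(section, params)
        idx = [ln.index for ln in lines]
        assert idx == sorted(idx)
        assert set(idx) <= set(range(64))


@pytest.fixture(scope="module")
def ellipse_lines():
    section = make_section(ellipse_points(15, 10, CENTER), ellipse_points(40, 28, CENTER),
                           n_points=64)
    params = tu.FieldLineParams(n_points=64, window=8, delta=1.0, rigidity=1,
                                k_max=150, v_min=1)
    return section, tu.trace_all(section, params)


class TestFieldLineGeometry:
    """Discrete analogues of the electrostatic guarantees."""

    def test_lines_do_not_cross(self, ellipse_lines):
        _, lines = ellipse_lines
        strings = [LineString(ln.points) for ln in lines]
        for a in range(len(strings)):
            b = (a + 1) % len(strings)  # adjacent lines are the crossing risk
            assert not strings[a].crosses(strings[b])

    def test_first_step_orthogonal_to_boundary(self, ellipse_lines):
        section, lines = ellipse_lines
        pts = section.inner.points
        n = len(pts)
        for ln in lines:
            u = pts[(ln.index + 1) % n] - pts[ln.index]
            u = u / np.linalg.norm(u)
            step = ln.points[1] - ln.points[0]
            step = step / np.linalg.norm(step)
            assert abs(np.dot(step, u)) < 0.05

    def test_symmetry_on_concentric_annulus(self, concentric_section, concentric_lines):
        d = np.array([ln.length for ln in concentric_lines])
        assert d.max() - d.min() < 1e-3
        # radial symmetry: rigidity changes the magnitudes, not the paths
        stiff = tu.trace_all(concentric_section,
                             tu.FieldLineParams(n_points=200, window=15, delta=2,
                                                rigidity=5.0, k_max=75, v_min=1))
        d_stiff = np.array([ln.length for ln in stiff])
        assert np.abs(d_stiff - d).max() < 1e-3

    def test_monotone_progress_away_from_inner(self, ellipse_lines):
        section, lines = ellipse_lines
        inner_ring = LineString(np.vstack([section.inner.points, section.inner.points[:1]]))
        from shapely.geometry import Point
        for ln in lines[::8]:
            dist = np.array([inner_ring.distance(Point(p)) for p in ln.points])
            assert np.all(np.diff(dist) > -1.0)  # within one step of monotone
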