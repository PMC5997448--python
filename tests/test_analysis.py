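"""Shape, twist, sliding and intercalation quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import chiratube as ct
from chiratube import analysis as an


def _regular_polygon(n, rx=1.0, ry=1.0, angle=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    xy = np.column_stack([rx * np.cos(t), ry * np.sin(t)])
    c, s = np.cos(angle), np.sin(angle)
    return xy @ np.array([[c, s], [-s, c]])


class TestMomentalEllipse:
    def test_near_circle_reports_zero_angle_and_deviation(self):
        theta, dev = an.polygon_axis_and_deviation(_regular_polygon(64))
        assert dev == pytest.approx(0.0, abs=1e-6)
        assert theta == 0.0

    def test_two_to_one_rectangle_closed_form(self):
        """A 2:1 rectangle's momental ellipse has axis ratio 2, so the
        circular-deviation index is (2-1)/(2+1) = 1/3."""
        rect = np.array([[-1, -0.5], [1, -0.5], [1, 0.5], [-1, 0.5]])
        theta, dev = an.polygon_axis_and_deviation(rect)
        assert dev == pytest.approx(1 / 3, abs=1e-12)
        assert theta == pytest.approx(90.0)    # long axis circumferential
        tall = rect[:, ::-1]
        theta2, dev2 = an.polygon_axis_and_deviation(tall)
        assert dev2 == pytest.approx(1 / 3, abs=1e-12)
        assert theta2 == pytest.approx(0.0, abs=1e-9)   # long axis axial

    @given(st.floats(-80.0, 80.0), st.integers(5, 9))
    @settings(max_examples=25, deadline=None, derandomize=True,
              database=None)
    def test_rotation_equivariance(self, alpha, n):
        poly = _regular_polygon(n, rx=1.7, ry=0.8)
        t0, d0 = an.polygon_axis_and_deviation(poly)
        a = np.radians(alpha)
        R = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
        t1, d1 = an.polygon_axis_and_deviation(poly @ R)
        assert d1 == pytest.approx(d0, abs=1e-9)
        # ccw rotation by alpha moves the axis from +y toward -x, i.e. the
        # angle-from-axis decreases by alpha (mod 180)
        dd = (t1 - (t0 - alpha) + 90.0) % 180.0 - 90.0
        assert dd == pytest.approx(0.0, abs=1e-6)

    def test_scale_invariance_of_deviation(self):
        poly = _regular_polygon(7, rx=2.0, ry=1.1)
        _, d0 = an.polygon_axis_and_deviation(poly)
        _, d1 = an.polygon_axis_and_deviation(poly * 13.7)
        assert d1 == pytest.approx(d0, rel=1e-12)

    def test_zero_area_rejected(self):
        degenerate = np.array([[0, 0], [1, 1], [2, 2]])
        with pytest.raises(ValueError):
            an.polygon_axis_and_deviation(degenerate)


class TestTwist:
    def test_self_reference_is_zero(self, fixture_tube):
        mesh = fixture_tube["mesh"]
        assert an.twist_angle(mesh, mesh) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_cancels(self, fixture_tube):
        mesh = fixture_tube["mesh"]
        rot = mesh.copy()
        a = np.radians(25.0)
        R = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        rot.positions = rot.positions @ R.T
        assert an.twist_angle(rot, mesh) == pytest.approx(0.0, abs=1e-9)

    def test_helical_map_calibration(self, fixture_tube):
        """phi += c*z twists the top ring by +c*H relative to the bottom in
        standard azimuth; viewed from the posterior end that is clockwise,
        so the reported twist is exactly -c*H (orientation contract)."""
        mesh = fixture_tube["mesh"]
        hel = mesh.copy()
        c = np.radians(1.5)     # 1.5 degrees per unit height
        p = hel.positions
        phi = np.arctan2(p[:, 1], p[:, 0]) + c * p[:, 2]
        r = np.hypot(p[:, 0], p[:, 1])
        hel.positions = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                                         p[:, 2]])
        H = p[:, 2].max() - p[:, 2].min()
        got = an.twist_angle(hel, mesh)
        assert got == pytest.approx(-1.5 * H, abs=1e-9)

    def test_topology_mismatch_rejected(self, fixture_tube, paper_tube):
        with pytest.raises(ValueError):
            an.twist_angle(fixture_tube["mesh"], paper_tube["mesh"])


class TestProjection:
    def test_unrolled_widths_equal_arc_lengths(self, fixture_tube):
        mesh = fixture_tube["mesh"]
        d = fixture_tube["diameter"]
        un = an.project_and_unroll(mesh, d)
        # on a perfect cylinder the unrolled planar areas reproduce the 3D
        # polygon areas up to arc-vs-chord stretching (a few percent at this
        # cell size)
        for i, poly in enumerate(un["polygons"]):
            x, y = poly[:, 0], poly[:, 1]
            area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
            fan = ct.polygon_area(mesh.faces[i], mesh.positions)
            assert area == pytest.approx(fan, rel=0.05)

    def test_peripheral_rows_flagged(self, fixture_tube):
        mesh = fixture_tube["mesh"]
        un = an.project_and_unroll(mesh, fixture_tube["diameter"])
        rows = an.face_rows_from_ends(mesh)
        assert np.array_equal(un["included"], rows > 2)
        assert un["included"].sum() > 0
        ring = set(mesh.cap_top) | set(mesh.cap_bottom)
        for fi, loop in enumerate(mesh.faces):
            if any(v in ring for v in loop):
                assert not un["included"][fi]

    def test_histogram_percentages_sum_to_100(self, rng):
        h = an.angle_histograms(rng.uniform(-89, 89, size=500))
        assert h["percent"].sum() == pytest.approx(100.0)

    def test_symmetric_angles_have_zero_bias(self):
        a = np.concatenate([np.linspace(-80, -10, 8), np.linspace(10, 80, 8)])
        assert an.angle_bias(a) == 0.0


class TestSliding:
    def _tracks(self, rows):
        return pd.DataFrame(rows, columns=["t", "cell", "x", "y"])

    def test_static_cells_have_zero_displacement(self):
        tracks = self._tracks([(0, 0, 1.0, 0.0), (0, 1, 1.0, 1.0),
                               (1, 0, 1.0, 0.0), (1, 1, 1.0, 1.0)])
        out = an.cell_sliding(tracks, [(1, 0)], interval=1.0)
        assert len(out) == 1 and out["dx"].iloc[0] == 0.0

    def test_upper_cell_moving_left_reports_negative(self):
        tracks = self._tracks([(0, 0, 0.0, 0.0), (0, 1, 0.0, 1.0),
                               (1, 0, 0.0, 0.0), (1, 1, -0.5, 1.0)])
        out = an.cell_sliding(tracks, [(1, 0)], interval=1.0)
        assert out["dx"].iloc[0] == pytest.approx(-0.5)

    def test_missing_time_point_skips_pair(self):
        tracks = self._tracks([(0, 0, 0.0, 0.0), (0, 1, 0.0, 1.0),
                               (1, 0, 0.0, 0.0)])
        out = an.cell_sliding(tracks, [(1, 0)], interval=1.0)
        assert len(out) == 0


class TestBoundaryTilt:
    def _angles(self, rows):
        return pd.DataFrame(rows, columns=["t", "boundary", "angle_deg"])

    def test_static_boundaries_unchanged(self):
        df = self._angles([(0, 0, 5.0), (1, 0, 5.0), (0, 1, -3.0), (1, 1, -3.0)])
        assert an.classify_boundary_tilt(df, 1.0) == {"ccw": 0, "uc": 2, "cw": 0}

    def test_positive_rotation_is_ccw(self):
        df = self._angles([(0, 0, 0.0), (1, 0, 5.0), (0, 1, 0.0), (1, 1, -5.0)])
        out = an.classify_boundary_tilt(df, 1.0, tol_deg=2.0)
        assert out == {"ccw": 1, "uc": 0, "cw": 1}

    def test_tolerance_bins_small_changes_as_unchanged(self):
        df = self._angles([(0, 0, 0.0), (1, 0, 1.5)])
        out = an.classify_boundary_tilt(df, 1.0, tol_deg=2.0)
        assert out["uc"] == 1


class TestIntercalationDetection:
    def test_no_topology_change_means_no_events(self, fixture_tube):
        mesh = fixture_tube["mesh"].copy()
        traj = ct.run(mesh, fixture_tube["params"],
                      ct.RunOptions(t_end=0.5, reconnect=False,
                                    save_every=0.25))
        assert an.detect_intercalations(traj) == []

    def test_detected_events_match_reconnection_log(self, fixture_tube):
        """Every intercalation found from the centroid/adjacency series
        corresponds to a logged neighbour-exchange whose separated faces
        are the same axially adjacent pair (cross-check of the detector
        against the simulator's own event log)."""
        mesh = fixture_tube["mesh"].copy()
        proto = ct.ChiralityProtocol(t_end_induction=1.5)
        mesh, _, _ = ct.build_chiral_tube(mesh, proto, fixture_tube["params"])
        ref = mesh.copy()
        pairs = an.axial_pairs(ref)
        traj = ct.run(mesh, fixture_tube["params"],
                      ct.RunOptions(t_end=3.0, save_every=0.25))
        found = an.detect_intercalations(traj, pairs,
                                         diameter=fixture_tube["diameter"])
        logged = {frozenset(e.faces_lost) for e in traj.events}
        for ev in found:
            assert frozenset((ev["upper"], ev["lower"])) in logged
            assert ev["direction"] in ("left", "right", "undetermined")
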