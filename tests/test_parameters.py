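"""Angle, displacement, speed, plane and peak-parameter computations."""
import numpy as np
import pytest

from kinemagree import (
    Plane, ReferenceFrame, TaskRecording, Annotations,
    displacement_series, estimate_ground_plane, joint_angle_series,
    jump_height, max_reach_distance, max_trunk_angles, midpoint_series,
    speed_series, trunk_rotation_series,
)
from conftest import make_trajectory, random_rigid

WORLD = ReferenceFrame(origin=(0, 0, 0), ml=(1, 0, 0), ap=(0, 1, 0),
                       vertical=(0, 0, 1))


def const(p, n=5):
    return np.tile(np.asarray(p, dtype=float), (n, 1))


def ts(n=5, fs=100.0):
    return np.arange(n) / fs


def all_valid(n=5):
    return np.ones(n, dtype=bool)


class TestJointAngle:
    def test_collinear_points_give_180(self):
        s = joint_angle_series(const((0, 0, 0)), const((1, 0, 0)), const((2, 0, 0)),
                               ts(), all_valid())
        assert np.allclose(s.values, 180.0)

    def test_perpendicular_rays_give_90(self):
        s = joint_angle_series(const((0, 1, 0)), const((0, 0, 0)), const((1, 0, 0)),
                               ts(), all_valid())
        assert np.allclose(s.values, 90.0)

    def test_invariant_under_rigid_transform_vs_dot_product_oracle(self, rng):
        for _ in range(25):
            a, b, c = (rng.uniform(-100, 100, 3) for _ in range(3))
            rot, shift = random_rigid(rng)
            s0 = joint_angle_series(const(a, 1), const(b, 1), const(c, 1),
                                    ts(1), all_valid(1))
            s1 = joint_angle_series(const(rot @ a + shift, 1), const(rot @ b + shift, 1),
                                    const(rot @ c + shift, 1), ts(1), all_valid(1))
            # brute-force oracle: arccos of the normalized dot product
            u, v = a - b, c - b
            oracle = np.degrees(np.arccos(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
            assert s0.values[0] == pytest.approx(oracle, abs=1e-9)
            assert s1.values[0] == pytest.approx(s0.values[0], abs=1e-9)

    def test_zero_length_ray_invalidates_frame_with_warning(self):
        with pytest.warns(UserWarning, match="zero-length"):
            s = joint_angle_series(const((0, 0, 0)), const((0, 0, 0)),
                                   const((1, 0, 0)), ts(), all_valid())
        assert not s.valid.any()


class TestTrunkRotation:
    def test_parallel_lines_give_zero(self):
        s = trunk_rotation_series(const((100, 0, 900)), const((-100, 0, 900)),
                                  const((200, 0, 1400)), const((-200, 0, 1400)),
                                  WORLD, ts(), all_valid())
        assert np.allclose(s.values, 0.0, atol=1e-9)

    @pytest.mark.parametrize("tilt_deg", [0.0, 20.0])
    def test_rotation_about_vertical_recovered_despite_tilt(self, tilt_deg):
        """30 deg yaw of the shoulder line reads 30 deg regardless of an
        additional tilt about the medio-lateral axis (horizontal projection)."""
        yaw = np.radians(30.0)
        tilt = np.radians(tilt_deg)
        rz = np.array([[np.cos(yaw), -np.sin(yaw), 0],
                       [np.sin(yaw), np.cos(yaw), 0], [0, 0, 1]])
        rx = np.array([[1, 0, 0], [0, np.cos(tilt), -np.sin(tilt)],
                       [0, np.sin(tilt), np.cos(tilt)]])
        sh_l = rx @ rz @ np.array([200.0, 0, 0])
        sh_r = rx @ rz @ np.array([-200.0, 0, 0])
        s = trunk_rotation_series(const((100, 0, 0)), const((-100, 0, 0)),
                                  const(sh_l), const(sh_r), WORLD, ts(), all_valid())
        # oracle: project both lines onto z=0 and measure the angle directly
        p = (rx @ rz @ np.array([1.0, 0, 0]))[:2]
        oracle = np.degrees(np.arccos(abs(p[0]) / np.linalg.norm(p)))
        assert s.values[0] == pytest.approx(oracle, abs=1e-9)
        if tilt_deg == 0:
            assert s.values[0] == pytest.approx(30.0, abs=1e-9)

    def test_vertical_shoulder_line_invalidates_frame(self):
        s = trunk_rotation_series(const((100, 0, 0)), const((-100, 0, 0)),
                                  const((0, 0, 200)), const((0, 0, -200)),
                                  WORLD, ts(), all_valid())
        assert not s.valid.any()


class TestDisplacement:
    def test_constant_position_zero_displacement(self):
        ml, v, ap = displacement_series(const((5, 6, 7), 10), WORLD, ts(10),
                                        all_valid(10), (0.0, 0.02))
        for s in (ml, v, ap):
            assert np.allclose(s.values, 0.0)

    def test_pure_vertical_drop(self):
        p = const((0, 0, 1000), 10)
        p[5:, 2] -= 200
        ml, v, ap = displacement_series(p, WORLD, ts(10), all_valid(10), (0.0, 0.04))
        assert np.allclose(v.values[5:], -200.0)
        assert np.allclose(ml.values, 0.0) and np.allclose(ap.values, 0.0)

    def test_helix_components_match_analytic_projections(self):
        t = ts(200)
        x = 50 * np.cos(2 * np.pi * t)
        y = 50 * np.sin(2 * np.pi * t)
        z = 300 * t
        p = np.column_stack([x, y, z])
        base = (0.0, 0.0)  # single-frame baseline: the t=0 position
        ml, v, ap = displacement_series(p, WORLD, t, all_valid(200), base)
        np.testing.assert_allclose(ml.values, x - 50, atol=1e-6)
        np.testing.assert_allclose(ap.values, y, atol=1e-6)
        np.testing.assert_allclose(v.values, z, atol=1e-6)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            displacement_series(const((0, 0, 0)), WORLD, ts(), all_valid(),
                                (10.0, 11.0))


class TestMidpointAndSpeed:
    def test_midpoint_identity_and_example(self):
        p = const((0, 0, 0))
        q = const((2, 4, 6))
        assert np.allclose(midpoint_series(p, p), p)
        assert np.allclose(midpoint_series(p, q), [1, 2, 3])

    def test_midpoint_commutes_with_rigid_transform(self, rng):
        p, q = rng.uniform(-50, 50, (2, 4, 3))
        rot, shift = random_rigid(rng)
        lhs = midpoint_series(p @ rot.T + shift, q @ rot.T + shift)
        rhs = midpoint_series(p, q) @ rot.T + shift
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_constant_position_zero_speed(self):
        s = speed_series(const((1, 2, 3), 10), ts(10), all_valid(10))
        assert np.allclose(s.values, 0.0)

    def test_uniform_motion_speed(self):
        t = ts(10)
        p = np.column_stack([100 * t, np.zeros_like(t), np.zeros_like(t)])
        s = speed_series(p, t, all_valid(10))
        assert np.allclose(s.values, 100.0)

    def test_circular_motion_speed_matches_analytic(self):
        t = np.arange(0, 1, 1 / 120)
        p = np.column_stack([100 * np.cos(2 * np.pi * t),
                             100 * np.sin(2 * np.pi * t), np.zeros_like(t)])
        s = speed_series(p, t, np.ones(len(t), dtype=bool))
        expected = 2 * np.pi * 100
        interior = s.values[1:-1]
        assert np.max(np.abs(interior - expected)) < 1e-3 * expected

    def test_frames_next_to_gap_invalidated(self):
        t = ts(10)
        valid = all_valid(10)
        valid[4] = False
        p = np.column_stack([100 * t, np.zeros_like(t), np.zeros_like(t)])
        s = speed_series(p, t, valid)
        assert not s.valid[3] and not s.valid[4] and not s.valid[5]
        assert s.valid[0] and s.valid[-1]

    def test_too_few_valid_frames_rejected(self):
        with pytest.raises(ValueError, match="3 valid"):
            speed_series(const((0, 0, 0), 2), ts(2), all_valid(2))


def _recording_with_feet(foot_l, foot_r, head=(0, 0, 1700), n=10):
    t = np.arange(n) / 100.0
    traj = make_trajectory({"head": head, "foot_l": foot_l, "foot_r": foot_r}, t)
    ann = Annotations(start=t[1], end=t[-1])
    return TaskRecording("P1", "jumping_jacks", "reference", traj, ann)


class TestGroundPlane:
    def test_flat_feet_give_upward_normal(self):
        # scatter the contact points so the plane is fully determined
        n = 10
        rng = np.random.default_rng(0)
        fl = np.column_stack([rng.uniform(50, 150, n), rng.uniform(-50, 50, n),
                              np.zeros(n)])
        fr = np.column_stack([rng.uniform(-150, -50, n), rng.uniform(-50, 50, n),
                              np.zeros(n)])
        rec = _recording_with_feet(fl, fr, n=n)
        plane = estimate_ground_plane(rec, (0.0, 0.1))
        assert np.allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert plane.signed_distance(np.array([[0.0, 0.0, 0.0]]))[0] == pytest.approx(0, abs=1e-9)

    def test_tilted_plane_recovered_within_point1_degree(self):
        n = 10
        rng = np.random.default_rng(1)
        tilt = np.radians(5.0)
        normal_true = np.array([np.sin(tilt), 0, np.cos(tilt)])
        pts = np.column_stack([rng.uniform(-200, 200, 2 * n),
                               rng.uniform(-200, 200, 2 * n), np.zeros(2 * n)])
        pts[:, 2] = -(pts[:, 0] * normal_true[0]) / normal_true[2]
        rec = _recording_with_feet(pts[:n], pts[n:], n=n)
        plane = estimate_ground_plane(rec, (0.0, 0.1))
        ang = np.degrees(np.arccos(np.clip(plane.normal @ normal_true, -1, 1)))
        assert ang < 0.1

    def test_collinear_foot_points_rejected(self):
        rec = _recording_with_feet((100, 0, 0), (-100, 0, 0))
        with pytest.raises(ValueError, match="collinear"):
            estimate_ground_plane(rec, (0.0, 0.1))


class TestPeaks:
    def test_wrist_on_plane_gives_zero_reach(self):
        n = 10
        peak = max_reach_distance(const((0, 100, 1400), n), const((200, 0, 1400), n),
                                  const((-200, 0, 1400), n), WORLD, ts(n),
                                  all_valid(n), (0.0, 0.02), (0.03, 0.09), "right")
        assert peak.value == pytest.approx(0.0, abs=1e-9)

    def test_programmed_crossing_recovered(self):
        n = 10
        wrist = const((-150, 100, 1400), n)
        wrist[6] = [250, 100, 1400]
        peak = max_reach_distance(wrist, const((200, 0, 1400), n),
                                  const((-200, 0, 1400), n), WORLD, ts(n),
                                  all_valid(n), (0.0, 0.02), (0.03, 0.09), "right")
        assert peak.value == pytest.approx(250.0, abs=1e-9)
        assert peak.frame_index == 6

    def test_upright_trunk_gives_zero_angles(self):
        n = 8
        windows = {d: (0.0, 0.07) for d in ("left", "right", "ventral", "dorsal")}
        peaks = max_trunk_angles(const((200, 0, 1400), n), const((-200, 0, 1400), n),
                                 const((100, 0, 900), n), const((-100, 0, 900), n),
                                 WORLD, ts(n), all_valid(n), windows)
        for p in peaks.values():
            assert p.value == pytest.approx(0.0, abs=1e-9)

    def test_pure_lateral_tilt_appears_only_in_frontal_plane(self):
        n = 8
        tilt = np.radians(25.0)
        top = np.array([500 * np.sin(tilt), 0.0, 900 + 500 * np.cos(tilt)])
        windows = {d: (0.0, 0.07) for d in ("left", "right", "ventral", "dorsal")}
        peaks = max_trunk_angles(const(top + [200, 0, 0], n), const(top - [200, 0, 0], n),
                                 const((100, 0, 900), n), const((-100, 0, 900), n),
                                 WORLD, ts(n), all_valid(n), windows)
        assert peaks["left"].value == pytest.approx(25.0, abs=1e-9)
        assert peaks["ventral"].value == pytest.approx(0.0, abs=1e-9)

    def test_combined_tilt_matches_projection_oracle(self):
        n = 4
        lat, ven = np.radians(20.0), np.radians(10.0)
        axis = np.array([np.sin(lat), np.cos(lat) * np.sin(ven),
                         np.cos(lat) * np.cos(ven)])
        top = 500 * axis + np.array([0, 0, 900])
        windows = {"left": (0.0, 0.03), "ventral": (0.0, 0.03)}
        peaks = max_trunk_angles(const(top + [200, 0, 0], n), const(top - [200, 0, 0], n),
                                 const((100, 0, 900), n), const((-100, 0, 900), n),
                                 WORLD, ts(n), all_valid(n), windows)
        # oracle: spherical projections of the tilted axis
        oracle_lat = np.degrees(np.arctan2(axis[0], axis[2]))
        oracle_ven = np.degrees(np.arctan2(axis[1], axis[2]))
        assert peaks["left"].value == pytest.approx(oracle_lat, abs=1e-6)
        assert peaks["ventral"].value == pytest.approx(oracle_ven, abs=1e-6)

    def test_jump_height_constant_clearance(self):
        n = 6
        plane = Plane((0, 0, 0), (0, 0, 1))
        peak = jump_height(const((100, 0, 50), n), const((-100, 0, 50), n),
                           plane, ts(n), all_valid(n), (0.0, 0.05))
        assert peak.value == pytest.approx(50.0, abs=1e-12)

    def test_jump_height_ignores_masked_apex(self):
        n = 6
        ankle = const((100, 0, 50), n)
        ankle[3] = [100, 0, 400]   # apex frame, masked below
        valid = all_valid(n)
        valid[3] = False
        plane = Plane((0, 0, 0), (0, 0, 1))
        peak = jump_height(ankle, const((-100, 0, 50), n), plane, ts(n), valid,
                           (0.0, 0.05))
        assert peak.value == pytest.approx(50.0, abs=1e-12)
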