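"""Containers, CSV/TRC I/O, resampling, rigid alignment, reference frames."""
import numpy as np
import pandas as pd
import pytest

from kinemagree import (
    JointTrajectorySet, build_reference_frame, estimate_rigid_transform,
    read_trajectories, resample_to, write_trajectories,
)
from conftest import make_trajectory, random_rigid


class TestContainers:
    def test_timestamps_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            make_trajectory({"head": (0, 0, 1700)}, [0.0, 0.2, 0.1])

    def test_unknown_joint_label_named_in_error(self):
        with pytest.raises(ValueError, match="sternum"):
            make_trajectory({"sternum": (0, 0, 0)}, [0.0, 0.1])

    def test_positions_must_be_finite_on_valid_frames(self):
        pos = np.zeros((1, 3, 3))
        pos[0, 1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            JointTrajectorySet(("head",), pos, [0.0, 0.1, 0.2], 10.0,
                               np.ones(3, dtype=bool))


class TestCsvIO:
    def test_three_frame_constant_head(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "time,head_x,head_y,head_z\n0.0,0,0,1700\n0.1,0,0,1700\n0.2,0,0,1700\n")
        traj = read_trajectories(path)
        assert traj.n_frames == 3
        assert np.allclose(traj.joint("head"), [0, 0, 1700])
        assert traj.valid.all()

    def test_missing_cells_mark_frame_invalid(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "time,wrist_l_x,wrist_l_y,wrist_l_z\n0.0,1,2,3\n0.1,,2,3\n0.2,1,2,3\n")
        traj = read_trajectories(path)
        assert traj.valid.tolist() == [True, False, True]

    def test_round_trip_bit_exact(self, tmp_path, rng):
        traj = make_trajectory(
            {"head": rng.uniform(-1000, 1000, (5, 3)),
             "hip_l": rng.uniform(-1000, 1000, (5, 3))},
            np.arange(5) / 30.0)
        path = tmp_path / "rt.csv"
        write_trajectories(traj, path)
        back = read_trajectories(path)
        assert back.joint_names == traj.joint_names
        np.testing.assert_array_equal(back.positions, traj.positions)
        np.testing.assert_array_equal(back.timestamps, traj.timestamps)

    def test_unknown_column_joint_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("time,pelvis_x,pelvis_y,pelvis_z\n0.0,0,0,0\n")
        with pytest.raises(ValueError, match="pelvis"):
            read_trajectories(path)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("time,head_x,head_y,head_z\n0.0,0,0,0\n0.0,0,0,0\n")
        with pytest.raises(ValueError, match="increasing"):
            read_trajectories(path)


class TestTrcIO:
    def test_reads_markers_and_metre_units(self, tmp_path):
        lines = [
            "PathFileType\t4\t(X/Y/Z)\tt.trc",
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits",
            "120\t120\t2\t2\tm",
            "Frame#\tTime\thead\t\t\tHIP_L\t\t",
            "\t\tX1\tY1\tZ1\tX2\tY2\tZ2",
            "1\t0.0\t0.0\t0.0\t1.7\t0.1\t0.0\t0.9",
            "2\t0.00833\t0.0\t0.0\t1.7\t0.1\t0.0\t0.9",
        ]
        path = tmp_path / "t.trc"
        path.write_text("\n".join(lines) + "\n")
        traj = read_trajectories(path, dialect="trc")
        assert traj.joint_names == ("head", "hip_l")
        assert np.allclose(traj.joint("head")[0], [0, 0, 1700])
        assert traj.rate == 120


class TestResample:
    def test_constant_resampled_anywhere(self):
        traj = make_trajectory({"head": (1, 2, 3)}, np.arange(11) / 10.0)
        out = resample_to(traj, [0.05, 0.512, 0.9])
        assert np.allclose(out.joint("head"), [1, 2, 3])
        assert out.valid.all()

    def test_linear_motion_interpolates_exactly(self):
        t = np.arange(0, 1.0001, 0.5)
        pos = np.column_stack([120 * t, np.zeros_like(t), np.zeros_like(t)])
        traj = make_trajectory({"head": pos}, t)
        out = resample_to(traj, [0.25])
        assert np.allclose(out.joint("head")[0], [30.0, 0.0, 0.0])

    def test_sine_downsampled_within_point1_percent(self):
        t120 = np.arange(0, 2.0001, 1 / 120)
        amp = 100.0
        pos = np.column_stack([amp * np.sin(2 * np.pi * t120),
                               np.zeros_like(t120), np.zeros_like(t120)])
        traj = make_trajectory({"head": pos}, t120)
        t30 = np.arange(0, 2.0001, 1 / 30)
        out = resample_to(traj, t30)
        analytic = amp * np.sin(2 * np.pi * t30)
        assert np.max(np.abs(out.joint("head")[:, 0] - analytic)) < 1e-3 * amp

    def test_identity_on_own_timestamps(self, rng):
        valid = np.ones(20, dtype=bool)
        valid[7] = False
        pos = rng.uniform(-100, 100, (20, 3))
        pos[7] = np.nan
        traj = make_trajectory({"head": pos}, np.arange(20) / 30.0, valid=valid)
        out = resample_to(traj, traj.timestamps)
        np.testing.assert_array_equal(out.valid, valid)
        np.testing.assert_allclose(out.joint("head")[valid], pos[valid])

    def test_target_between_valid_and_invalid_frame_is_invalid(self):
        valid = np.array([True, False, True, True])
        pos = np.array([[0, 0, 0], [np.nan] * 3, [2, 0, 0], [3, 0, 0]], dtype=float)
        traj = make_trajectory({"head": pos}, [0.0, 0.1, 0.2, 0.3], valid=valid)
        out = resample_to(traj, [0.05, 0.25])
        assert out.valid.tolist() == [False, True]
        # bridged across the gap between nearest valid frames
        assert np.allclose(out.joint("head")[1], [2.5, 0, 0])

    def test_extrapolation_rejected(self):
        traj = make_trajectory({"head": (0, 0, 0)}, [0.0, 0.1])
        with pytest.raises(ValueError, match="span"):
            resample_to(traj, [0.2])


class TestRigidTransform:
    def test_identical_point_sets_give_identity(self, rng):
        pts = rng.uniform(-100, 100, (6, 3))
        tr = estimate_rigid_transform(pts, pts)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0, atol=1e-10)

    def test_recovers_constructed_rotation_translation(self, rng):
        pts = rng.uniform(-100, 100, (5, 3))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        shift = np.array([10.0, 0.0, 0.0])
        tr = estimate_rigid_transform(pts, pts @ rot.T + shift)
        assert np.allclose(tr.rotation, rot, atol=1e-12)
        assert np.allclose(tr.translation, shift, atol=1e-9)

    def test_noisy_cloud_alignment_reduces_rmsd(self, rng):
        for _ in range(20):
            src = rng.uniform(-200, 200, (8, 3))
            rot, shift = random_rigid(rng)
            dst = src @ rot.T + shift + rng.normal(0, 1.0, (8, 3))
            tr = estimate_rigid_transform(src, dst)
            aligned = tr.apply(src)
            rmsd_post = np.sqrt(np.mean(np.sum((aligned - dst) ** 2, axis=1)))
            rmsd_pre = np.sqrt(np.mean(np.sum((src - dst) ** 2, axis=1)))
            assert rmsd_post <= rmsd_pre + 1e-9
            assert rmsd_post <= 2.0

    def test_compose_with_inverse_is_identity(self, rng):
        rot, shift = random_rigid(rng)
        tr = estimate_rigid_transform(
            rng.uniform(-10, 10, (4, 3)),
            rng.uniform(-10, 10, (4, 3)))
        both = tr.compose(tr.inverse())
        assert np.allclose(both.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(both.translation, 0, atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            estimate_rigid_transform(pts, pts)


def _standing_traj(yaw_deg=0.0, noise_sd=0.0, rng=None, n=50):
    c, s = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    pts = {
        "shoulder_l": rot @ [200, 0, 1400], "shoulder_r": rot @ [-200, 0, 1400],
        "hip_l": rot @ [100, 0, 900], "hip_r": rot @ [-100, 0, 900],
    }
    t = np.arange(n) / 100.0
    arrays = {}
    for k, p in pts.items():
        arr = np.tile(p, (n, 1))
        if noise_sd and rng is not None:
            arr = arr + rng.normal(0, noise_sd, arr.shape)
        arrays[k] = arr
    return make_trajectory(arrays, t)


class TestReferenceFrame:
    def test_upright_pose_gives_world_axes(self):
        frame = build_reference_frame(_standing_traj(), (0.0, 0.5), (0, 0, -1))
        assert np.allclose(frame.ml, [1, 0, 0], atol=1e-12)
        assert np.allclose(frame.ap, [0, 1, 0], atol=1e-12)
        assert np.allclose(frame.vertical, [0, 0, 1], atol=1e-12)
        assert np.allclose(frame.origin, [0, 0, 900], atol=1e-9)

    def test_rotated_pose_rotates_ml_axis(self):
        frame = build_reference_frame(_standing_traj(yaw_deg=45), (0.0, 0.5), (0, 0, -1))
        expected = np.array([np.cos(np.radians(45)), np.sin(np.radians(45)), 0.0])
        assert np.allclose(frame.ml, expected, atol=1e-12)

    def test_noisy_standing_window_axes_within_one_degree(self, rng):
        for _ in range(10):
            frame = build_reference_frame(
                _standing_traj(noise_sd=5.0, rng=rng), (0.0, 0.5), (0, 0, -1))
            ang = np.degrees(np.arccos(np.clip(frame.ml @ [1, 0, 0], -1, 1)))
            assert ang < 1.0

    def test_axes_orthonormal_for_arbitrary_gravity(self, rng):
        g = rng.standard_normal(3)
        g[2] = -abs(g[2]) - 1.0
        frame = build_reference_frame(_standing_traj(), (0.0, 0.5), g)
        axes = np.stack([frame.ml, frame.ap, frame.vertical])
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-9)

    def test_shoulder_line_parallel_to_gravity_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            build_reference_frame(_standing_traj(), (0.0, 0.5), (-1, 0, 0))
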