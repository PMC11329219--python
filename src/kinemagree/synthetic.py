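"""Synthetic two-system motion-capture study generator.

This module stands in for a validation study in which participants perform
five movement tasks (reach across the midline, trunk bending, standing
straight leg raise, squats, jumping jacks) while being recorded simultaneously
by a high-rate, low-noise reference system (marker-based, 120 Hz) and a
lower-rate, noisier test system (markerless RGB-D, 30 Hz).

Noise-free choreography
-----------------------
Each participant is a stick-figure :class:`SkeletonModel` whose neutral
standing pose is derived from stature by fixed anthropometric ratios. Moving
joints follow piecewise minimum-jerk segments between key poses: within a
segment the travelled fraction is s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5
(speed profile 30 tau^2 - 60 tau^3 + 30 tau^4 scaled by distance/duration),
the classic smooth point-to-point primitive with zero velocity and
acceleration at both ends — so concatenated segments are C^1 (indeed C^2)
continuous and their smoothness under spectral measures is well
characterised. Key poses are placed on a 0.1 s grid so that the 240 Hz
internal sampling and both observation grids (120 and 30 Hz) hit every pose
extreme exactly; programmed peak values are therefore attained, not merely
approached, on every grid.

Every task returns the ground-truth values of the peak parameters it is
scored on (max reach distance, max trunk angles, squat peak knee-flexion
angle, jump apex height), plus annotations (movement start/end, repetition
boundaries) taken from the known choreography.

Observation model
-----------------
:func:`observe` samples the noise-free choreography at a system's rate and
adds i.i.d. per-axis Gaussian noise. The test system can additionally be
expressed in a rotated/translated camera frame (exercising the rigid
alignment step), drop frames entirely (body not detected), and suffer short
"jump" artifacts in which one limb's joints are displaced coherently for a
fraction of a second — the characteristic failure mode of consumer body
trackers losing a limb.

All randomness flows through one seeded generator; identical config + seed
gives bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .parameters import COM_WEIGHTS
from .trajectories import (
    CANONICAL_JOINTS, TASKS, Annotations, JointTrajectorySet, TaskRecording,
    resample_to,
)

__all__ = [
    "SkeletonModel", "TaskParams", "ObservationParams", "SyntheticConfig",
    "StudySet", "minimum_jerk", "generate_task", "observe", "generate_study",
]

#: Neutral-pose joint heights / offsets as fractions of stature. Only the
#: relative geometry matters for the parameters scored here.
ANTHROPOMETRIC_RATIOS = {
    "head_height": 0.936,
    "shoulder_height": 0.818,
    "shoulder_half_width": 0.129,
    "elbow_height": 0.630,
    "elbow_half_width": 0.140,
    "wrist_height": 0.485,
    "wrist_half_width": 0.150,
    "hip_height": 0.530,
    "hip_half_width": 0.0955,
    "knee_height": 0.285,
    "ankle_height": 0.039,
    "foot_forward": 0.120,
}

_UPPER_JOINTS = ("head", "shoulder_l", "shoulder_r", "elbow_l", "elbow_r",
                 "wrist_l", "wrist_r")
_LIMBS = {
    "arm_l": ("elbow_l", "wrist_l"),
    "arm_r": ("elbow_r", "wrist_r"),
    "leg_l": ("knee_l", "ankle_l", "foot_l"),
    "leg_r": ("knee_r", "ankle_r", "foot_r"),
}


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on tau in [0, 1]."""
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


class _Channel:
    """Piecewise minimum-jerk interpolation through (time, value) key poses.

    Values may be scalars or 3-vectors; before the first / after the last key
    the channel holds the boundary value.
    """

    def __init__(self, keys):
        times = np.array([k[0] for k in keys], dtype=float)
        if not np.all(np.diff(times) > 0):
            raise ValueError("key times must be strictly increasing")
        self.times = times
        self.values = np.array([np.asarray(k[1], dtype=float) for k in keys])

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        seg = np.clip(np.searchsorted(self.times, t, side="right") - 1,
                      0, len(self.times) - 2)
        t0, t1 = self.times[seg], self.times[seg + 1]
        tau = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
        s = minimum_jerk(tau)
        v0, v1 = self.values[seg], self.values[seg + 1]
        if self.values.ndim == 2:
            s = s[:, None]
        return v0 + (v1 - v0) * s


@dataclass(frozen=True)
class SkeletonModel:
    """Stick-figure anthropometry: a neutral standing pose scaled to stature."""

    stature_mm: float

    def __post_init__(self):
        if self.stature_mm <= 0:
            raise ValueError("stature must be positive")

    def neutral_pose(self) -> dict[str, np.ndarray]:
        """Neutral standing pose; +x medio-lateral (left), +y anterior,
        +z vertical (up); feet on the ground plane z = 0."""
        s = self.stature_mm
        r = ANTHROPOMETRIC_RATIOS
        pose = {"head": np.array([0.0, 0.0, r["head_height"] * s])}
        for side, sgn in (("l", 1.0), ("r", -1.0)):
            pose[f"shoulder_{side}"] = np.array(
                [sgn * r["shoulder_half_width"] * s, 0.0, r["shoulder_height"] * s])
            pose[f"elbow_{side}"] = np.array(
                [sgn * r["elbow_half_width"] * s, 0.0, r["elbow_height"] * s])
            pose[f"wrist_{side}"] = np.array(
                [sgn * r["wrist_half_width"] * s, 0.0, r["wrist_height"] * s])
            for joint, height in (("hip", "hip_height"), ("knee", "knee_height"),
                                  ("ankle", "ankle_height")):
                pose[f"{joint}_{side}"] = np.array(
                    [sgn * r["hip_half_width"] * s, 0.0, r[height] * s])
            pose[f"foot_{side}"] = np.array(
                [sgn * r["hip_half_width"] * s, r["foot_forward"] * s, 0.0])
        return pose

    @property
    def thigh_length_mm(self) -> float:
        r = ANTHROPOMETRIC_RATIOS
        return (r["hip_height"] - r["knee_height"]) * self.stature_mm

    @property
    def shank_length_mm(self) -> float:
        r = ANTHROPOMETRIC_RATIOS
        return (r["knee_height"] - r["ankle_height"]) * self.stature_mm

    @property
    def ankle_height_mm(self) -> float:
        return ANTHROPOMETRIC_RATIOS["ankle_height"] * self.stature_mm

    @property
    def shoulder_height_mm(self) -> float:
        return ANTHROPOMETRIC_RATIOS["shoulder_height"] * self.stature_mm


@dataclass(frozen=True)
class TaskParams:
    """Choreography parameters of the five tasks (mm, deg, s, counts)."""

    reach_excursion_mm: float = 300.0
    reach_target_height_frac: float = 0.818   # shoulder height
    trunk_rotation_max_deg: float = 30.0
    trunk_bend_amplitudes_deg: tuple[float, float, float, float] = (25.0, 25.0, 30.0, 15.0)
    leg_raise_angle_deg: float = 40.0
    leg_raise_hold_s: float = 3.0
    weight_shift_mm: float = 60.0
    squat_knee_min_angle_deg: float = 90.0
    n_squats: int = 3
    n_jumps: int = 3
    jump_rise_mm: float = 150.0
    jump_ankle_spread_mm: float = 250.0

    def __post_init__(self):
        if self.n_squats < 1 or self.n_jumps < 1:
            raise ValueError("repetition counts must be >= 1")
        if not (0 < self.squat_knee_min_angle_deg < 180):
            raise ValueError("squat knee angle must lie in (0, 180) degrees")
        if self.leg_raise_hold_s <= 0:
            raise ValueError("leg raise hold must be positive")


@dataclass(frozen=True)
class ObservationParams:
    """One capture system's observation model."""

    rate_hz: float
    noise_sd_mm: float = 0.0
    dropout_prob: float = 0.0
    jump_prob: float = 0.0
    jump_magnitude_mm: float = 150.0
    jump_duration_s: float = 0.25
    camera_yaw_deg: float = 0.0
    camera_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise SD must be non-negative")
        for p in (self.dropout_prob, self.jump_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


#: Default per-axis test-system noise SD (mm). Chosen so that the mean 3D
#: joint position error, sigma * 2 * sqrt(2/pi) for isotropic Gaussian noise,
#: is ~11.7 mm — the test method's previously reported joint position error.
TEST_NOISE_SD_MM = 7.3

_DEFAULT_REFERENCE = ObservationParams(rate_hz=120.0, noise_sd_mm=0.5)
_DEFAULT_TEST = ObservationParams(
    rate_hz=30.0, noise_sd_mm=TEST_NOISE_SD_MM,
    dropout_prob=0.002, jump_prob=0.001,
    jump_magnitude_mm=150.0, jump_duration_s=0.25,
    camera_yaw_deg=15.0, camera_offset_mm=(300.0, -2000.0, 0.0),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the virtual study."""

    n_participants: int = 23
    stature_range_mm: tuple[float, float] = (1100.0, 1890.0)
    task_params: TaskParams = field(default_factory=TaskParams)
    reference: ObservationParams = field(default_factory=lambda: _DEFAULT_REFERENCE)
    test: ObservationParams = field(default_factory=lambda: _DEFAULT_TEST)
    tasks: tuple[str, ...] = TASKS
    internal_rate_hz: float = 240.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "tasks", tuple(self.tasks))
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        lo, hi = self.stature_range_mm
        if not (0 < lo <= hi):
            raise ValueError("invalid stature range")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task: {t!r}")
        if self.internal_rate_hz <= 0:
            raise ValueError("internal rate must be positive")


# ---------------------------------------------------------------------------
# Task choreographies
# ---------------------------------------------------------------------------

def _rot_about(axis: str, deg: np.ndarray) -> np.ndarray:
    """Stack of rotation matrices about a principal axis, shape (n, 3, 3)."""
    a = np.radians(np.asarray(deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    n = len(a)
    m = np.zeros((n, 3, 3))
    i, j, k = {"x": (0, 1, 2), "y": (1, 2, 0), "z": (2, 0, 1)}[axis]
    m[:, i, i] = 1.0
    m[:, j, j] = c
    m[:, k, k] = c
    m[:, k, j] = s
    m[:, j, k] = -s
    return m


def _rotate_about_pivot(point: np.ndarray, pivot: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Apply per-frame rotations (n,3,3) to a fixed point about a pivot."""
    return pivot + np.einsum("nij,j->ni", rot, point - pivot)


class _Choreography:
    """Accumulates per-joint position arrays over the internal time grid."""

    def __init__(self, skeleton: SkeletonModel, duration_s: float, rate_hz: float):
        if abs(duration_s * 10 - round(duration_s * 10)) > 1e-9:
            raise ValueError("choreography durations must be multiples of 0.1 s")
        self.t = np.arange(int(round(duration_s * rate_hz)) + 1) / rate_hz
        self.pose = skeleton.neutral_pose()
        n = len(self.t)
        self.joints = {name: np.tile(p, (n, 1)) for name, p in self.pose.items()}

    def set_channel(self, joint: str, keys) -> None:
        full = [(self.t[0], self.pose[joint])] if keys[0][0] > self.t[0] else []
        self.joints[joint] = _Channel(full + list(keys))(self.t)

    def finish(self) -> JointTrajectorySet:
        com = np.zeros((len(self.t), 3))
        for j, w in COM_WEIGHTS.items():
            com += w * self.joints[j]
        self.joints["com"] = com
        names = tuple(j for j in CANONICAL_JOINTS if j in self.joints)
        pos = np.stack([self.joints[j] for j in names])
        rate = 1.0 / (self.t[1] - self.t[0])
        return JointTrajectorySet(names, pos, self.t, rate,
                                  np.ones(len(self.t), dtype=bool))


def _build_reach(skel: SkeletonModel, p: TaskParams, rate: float):
    s = skel.stature_mm
    cho = _Choreography(skel, 7.1, rate)
    pose = cho.pose
    target_z = p.reach_target_height_frac * s

    # right arm reaches across to the left (+x), then the left arm mirrors
    for side, sgn, t0 in (("r", +1.0, 1.0), ("l", -1.0, 3.9)):
        wrist = f"wrist_{side}"
        elbow = f"elbow_{side}"
        w_target = np.array([sgn * p.reach_excursion_mm, 0.30 * s, target_z])
        e_target = np.array([sgn * 0.4 * p.reach_excursion_mm, 0.18 * s, 0.75 * s])
        cho.set_channel(wrist, [(t0, pose[wrist]), (t0 + 1.2, w_target),
                                (t0 + 1.5, w_target), (t0 + 2.7, pose[wrist])])
        cho.set_channel(elbow, [(t0, pose[elbow]), (t0 + 1.2, e_target),
                                (t0 + 1.5, e_target), (t0 + 2.7, pose[elbow])])

    # trunk rotation about the vertical axis through the mid-shoulder point
    th = p.trunk_rotation_max_deg
    theta = _Channel([(0.0, 0.0), (1.0, 0.0), (2.2, th), (2.5, th), (3.7, 0.0),
                      (3.9, 0.0), (5.1, -th), (5.4, -th), (6.6, 0.0)])(cho.t)
    pivot = 0.5 * (pose["shoulder_l"] + pose["shoulder_r"])
    rot = _rot_about("z", theta)
    for j in ("shoulder_l", "shoulder_r"):
        cho.joints[j] = _rotate_about_pivot(pose[j], pivot, rot)

    ann = Annotations(start=1.0, end=6.6)
    truth = {"max_reach_distance": p.reach_excursion_mm}
    return cho, ann, truth


def _build_trunk_bending(skel: SkeletonModel, p: TaskParams, rate: float):
    amp_l, amp_r, amp_v, amp_d = p.trunk_bend_amplitudes_deg
    cho = _Choreography(skel, 10.7, rate)
    pose = cho.pose
    # one bend per direction: 1.0 s out, 0.3 s hold, 1.0 s back
    lat = _Channel([(0.0, 0.0), (1.0, 0.0), (2.0, amp_l), (2.3, amp_l), (3.3, 0.0),
                    (4.3, -amp_r), (4.6, -amp_r), (5.6, 0.0)])(cho.t)
    sag = _Channel([(0.0, 0.0), (5.6, 0.0), (6.6, amp_v), (6.9, amp_v), (7.9, 0.0),
                    (8.9, -amp_d), (9.2, -amp_d), (10.2, 0.0)])(cho.t)
    pivot = 0.5 * (pose["hip_l"] + pose["hip_r"])
    # lateral bend rotates about the anterio-posterior (y) axis, sagittal
    # about the medio-lateral (x) axis; only one is nonzero at a time
    rot = np.einsum("nij,njk->nik", _rot_about("y", lat), _rot_about("x", sag))
    for j in _UPPER_JOINTS:
        cho.joints[j] = _rotate_about_pivot(pose[j], pivot, rot)
    ann = Annotations(start=1.0, end=10.2, reps=(3.3, 5.6, 7.9))
    truth = {"trunk_angle_left": amp_l, "trunk_angle_right": amp_r,
             "trunk_angle_ventral": amp_v, "trunk_angle_dorsal": amp_d}
    return cho, ann, truth


def _build_sslr(skel: SkeletonModel, p: TaskParams, rate: float):
    hold = p.leg_raise_hold_s
    if abs(hold * 10 - round(hold * 10)) > 1e-9:
        raise ValueError("leg raise hold must be a multiple of 0.1 s")
    t_rel = [1.0, 2.0, 2.0 + hold, 3.0 + hold]          # raise, hold, lower
    dur = 3.0 + hold
    total = t_rel[3] + dur + 0.5
    cho = _Choreography(skel, total, rate)
    pose = cho.pose
    shift = _Channel([
        (0.0, 0.0), (t_rel[0], 0.0), (t_rel[1], p.weight_shift_mm),
        (t_rel[2], p.weight_shift_mm), (t_rel[3], 0.0),
        (t_rel[1] + dur, -p.weight_shift_mm), (t_rel[2] + dur, -p.weight_shift_mm),
        (t_rel[3] + dur, 0.0),
    ])(cho.t)
    for j in (*_UPPER_JOINTS, "hip_l", "hip_r"):
        cho.joints[j] = pose[j] + np.outer(shift, np.array([1.0, 0.0, 0.0]))
    for side, t0 in (("r", 1.0), ("l", 1.0 + dur)):
        phi = _Channel([(0.0, 0.0), (t0, 0.0), (t0 + 1.0, p.leg_raise_angle_deg),
                        (t0 + 1.0 + hold, p.leg_raise_angle_deg),
                        (t0 + 2.0 + hold, 0.0)])(cho.t)
        rot = _rot_about("x", phi)
        hip = cho.joints[f"hip_{side}"]
        for j in (f"knee_{side}", f"ankle_{side}", f"foot_{side}"):
            offset = pose[j] - pose[f"hip_{side}"]
            cho.joints[j] = hip + np.einsum("nij,j->ni", rot, offset)
    ann = Annotations(start=1.0, end=total - 0.5, reps=(1.0 + dur,))
    return cho, ann, {}


def _squat_geometry(skel: SkeletonModel, beta: np.ndarray):
    """Leg geometry for shank tilt ``beta`` (rad): the ankle stays fixed, the
    knee moves forward along the shank, the hip stays above the ankle."""
    ls, lt = skel.shank_length_mm, skel.thigh_length_mm
    knee_y = ls * np.sin(beta)
    knee_z = skel.ankle_height_mm + ls * np.cos(beta)
    arg = lt**2 - knee_y**2
    if np.any(arg <= 0):
        raise ValueError("squat depth exceeds leg geometry")
    hip_z = knee_z + np.sqrt(arg)
    return knee_y, knee_z, hip_z


def _squat_knee_angle(skel: SkeletonModel, beta: float) -> float:
    knee_y, knee_z, hip_z = _squat_geometry(skel, np.atleast_1d(float(beta)))
    knee = np.array([0.0, knee_y[0], knee_z[0]])
    hip = np.array([0.0, 0.0, hip_z[0]])
    ankle = np.array([0.0, 0.0, skel.ankle_height_mm])
    u, v = hip - knee, ankle - knee
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _build_squat(skel: SkeletonModel, p: TaskParams, rate: float):
    ls, lt = skel.shank_length_mm, skel.thigh_length_mm
    beta_lim = float(np.arcsin(min(1.0, lt / ls))) - 1e-3
    alpha_target = p.squat_knee_min_angle_deg
    if _squat_knee_angle(skel, beta_lim) > alpha_target:
        raise ValueError("programmed squat depth exceeds leg geometry")
    beta_max = brentq(lambda b: _squat_knee_angle(skel, b) - alpha_target,
                      1e-9, beta_lim)

    n, cycle = p.n_squats, 2.7                          # 1.2 down, 0.3 hold, 1.2 up
    t_sq0, t_sq1 = 2.0, 2.0 + n * cycle
    total = t_sq1 + 1.5
    cho = _Choreography(skel, total, rate)
    pose = cho.pose

    keys = [(0.0, 0.0), (t_sq0, 0.0)]
    for k in range(n):
        t0 = t_sq0 + k * cycle
        keys += [(t0 + 1.2, beta_max), (t0 + 1.5, beta_max), (t0 + 2.7, 0.0)]
    beta = _Channel(keys)(cho.t)

    knee_y, knee_z, hip_z = _squat_geometry(skel, beta)
    drop = pose["hip_l"][2] - hip_z
    for side in ("l", "r"):
        x = pose[f"hip_{side}"][0]
        cho.joints[f"knee_{side}"] = np.column_stack(
            [np.full_like(knee_y, x), knee_y, knee_z])
        cho.joints[f"hip_{side}"] = np.column_stack(
            [np.full_like(hip_z, x), np.zeros_like(hip_z), hip_z])
    # torso follows the pelvis down, with a slight forward lean and lateral
    # sway proportional to depth so all displacement components carry signal
    torso_offset = np.column_stack([0.03 * drop, 0.25 * drop, -drop])
    for j in ("head", "shoulder_l", "shoulder_r"):
        cho.joints[j] = pose[j] + torso_offset

    # arms stretched out to the front during the squats
    s = skel.stature_mm
    for side, sgn in (("l", 1.0), ("r", -1.0)):
        wrist, elbow = f"wrist_{side}", f"elbow_{side}"
        w_front = np.array([sgn * 0.129 * s, 0.55 * 0.818 * s, 0.818 * s])
        e_front = np.array([sgn * 0.129 * s, 0.28 * 0.818 * s, 0.818 * s])
        arm_w = _Channel([(0.0, pose[wrist]), (1.0, pose[wrist]), (2.0, w_front),
                          (t_sq1, w_front), (t_sq1 + 1.0, pose[wrist])])(cho.t)
        arm_e = _Channel([(0.0, pose[elbow]), (1.0, pose[elbow]), (2.0, e_front),
                          (t_sq1, e_front), (t_sq1 + 1.0, pose[elbow])])(cho.t)
        cho.joints[wrist] = arm_w + torso_offset
        cho.joints[elbow] = arm_e + torso_offset

    # movement includes the arm raise so the pre-movement window stays static
    reps = tuple(t_sq0 + k * cycle for k in range(1, n))
    ann = Annotations(start=1.0, end=t_sq1 + 1.0, reps=reps)
    truth = {"knee_angle_peak_flexion": alpha_target}
    return cho, ann, truth


def _build_jumping_jacks(skel: SkeletonModel, p: TaskParams, rate: float):
    s = skel.stature_mm
    n, cycle = p.n_jumps, 1.2
    t0_all, t1_all = 1.0, 1.0 + n * cycle
    cho = _Choreography(skel, t1_all + 0.5, rate)
    pose = cho.pose
    rise = p.jump_rise_mm
    spread = p.jump_ankle_spread_mm / 2.0

    overhead = {"l": np.array([0.08 * s, 0.0, 1.15 * s]),
                "r": np.array([-0.08 * s, 0.0, 1.15 * s])}
    t_pose = {"l": np.array([0.46 * s, 0.0, 0.818 * s]),
              "r": np.array([-0.46 * s, 0.0, 0.818 * s])}

    for side, sgn in (("l", 1.0), ("r", -1.0)):
        ankle, foot, knee = f"ankle_{side}", f"foot_{side}", f"knee_{side}"
        wrist, elbow = f"wrist_{side}", f"elbow_{side}"
        a0 = pose[ankle]
        out = np.array([sgn * spread, 0.0, 0.0])
        up = np.array([0.0, 0.0, rise])
        ankle_keys, wrist_keys = [(0.0, a0)], [(0.0, pose[wrist])]
        for k in range(n):
            t0 = t0_all + k * cycle
            ankle_keys += [(t0, a0), (t0 + 0.3, a0 + out + up), (t0 + 0.6, a0 + out),
                           (t0 + 0.9, a0 + up), (t0 + 1.2, a0)]
            wrist_keys += [(t0, pose[wrist]), (t0 + 0.3, t_pose[side]),
                           (t0 + 0.6, overhead[side]), (t0 + 0.9, t_pose[side]),
                           (t0 + 1.2, pose[wrist])]
        # drop duplicated segment-boundary keys
        ankle_keys = [k for i, k in enumerate(ankle_keys)
                      if i == 0 or k[0] > ankle_keys[i - 1][0]]
        wrist_keys = [k for i, k in enumerate(wrist_keys)
                      if i == 0 or k[0] > wrist_keys[i - 1][0]]
        cho.set_channel(ankle, ankle_keys)
        cho.set_channel(wrist, wrist_keys)
        cho.joints[foot] = cho.joints[ankle] + (pose[foot] - pose[ankle])
        # knees follow the ankles at half excursion (hip end stays put)
        cho.joints[knee] = pose[knee] + 0.5 * (cho.joints[ankle] - a0)
        cho.joints[elbow] = pose[elbow] + 0.5 * (cho.joints[wrist] - pose[wrist])

    # whole-trunk rise during the airborne phases
    rise_keys = [(0.0, 0.0)]
    for k in range(n):
        t0 = t0_all + k * cycle
        rise_keys += [(t0, 0.0), (t0 + 0.3, 0.5 * rise), (t0 + 0.6, 0.0),
                      (t0 + 0.9, 0.5 * rise), (t0 + 1.2, 0.0)]
    rise_keys = [k for i, k in enumerate(rise_keys)
                 if i == 0 or k[0] > rise_keys[i - 1][0]]
    lift = _Channel(rise_keys)(cho.t)
    for j in ("head", "shoulder_l", "shoulder_r", "hip_l", "hip_r"):
        cho.joints[j] = cho.joints[j] + np.outer(lift, np.array([0.0, 0.0, 1.0]))

    reps = tuple(t0_all + k * cycle for k in range(1, n))
    ann = Annotations(start=t0_all, end=t1_all, reps=reps)
    truth = {"jump_height": skel.ankle_height_mm + rise}
    return cho, ann, truth


_BUILDERS = {
    "reach": _build_reach,
    "trunk_bending": _build_trunk_bending,
    "sslr": _build_sslr,
    "squat": _build_squat,
    "jumping_jacks": _build_jumping_jacks,
}


def generate_task(skeleton: SkeletonModel, task: str, params: TaskParams,
                  participant_id: str = "P00", internal_rate_hz: float = 240.0
                  ) -> tuple[TaskRecording, dict[str, float]]:
    """Noise-free choreography for one task, sampled at the internal rate.

    Returns the truth recording (``system='truth'``) and the ground-truth
    values of every peak parameter the task is scored on.
    """
    if task not in _BUILDERS:
        raise ValueError(f"unknown task: {task!r}")
    cho, ann, truth = _BUILDERS[task](skeleton, params, internal_rate_hz)
    traj = cho.finish()
    rec = TaskRecording(participant_id, task, "truth", traj, ann)
    return rec, truth


# ---------------------------------------------------------------------------
# Observation model
# ---------------------------------------------------------------------------

def observe(truth: TaskRecording, system: str, params: ObservationParams,
            rng: np.random.Generator) -> TaskRecording:
    """Render a noise-free recording through one system's observation model."""
    if system not in ("reference", "test"):
        raise ValueError("system must be 'reference' or 'test'")
    src = truth.trajectories
    duration = src.timestamps[-1]
    n = int(round(duration * params.rate_hz)) + 1
    ts = np.arange(n) / params.rate_hz
    sampled = resample_to(src, ts)
    pos = sampled.positions.copy()

    # camera pose: world -> system coordinates
    yaw = np.radians(params.camera_yaw_deg)
    if yaw != 0.0 or any(params.camera_offset_mm):
        c, s = np.cos(yaw), np.sin(yaw)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        pos = pos @ rot.T + np.asarray(params.camera_offset_mm, dtype=float)

    # per-axis Gaussian noise; standard normals are always drawn so that runs
    # differing only in noise SD share the same underlying draws
    eps = rng.standard_normal(pos.shape)
    pos = pos + params.noise_sd_mm * eps

    valid = sampled.valid.copy()
    if params.jump_prob > 0:
        starts = np.flatnonzero(rng.random(n) < params.jump_prob)
        run = max(1, int(round(params.jump_duration_s * params.rate_hz)))
        limb_names = list(_LIMBS)
        for i in starts:
            limb = limb_names[int(rng.integers(len(limb_names)))]
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            sl = slice(i, min(n, i + run))
            for j in _LIMBS[limb]:
                if j in sampled.joint_names:
                    pos[sampled.joint_names.index(j), sl] += \
                        params.jump_magnitude_mm * direction
    if params.dropout_prob > 0:
        dropped = rng.random(n) < params.dropout_prob
        valid &= ~dropped
        pos[:, ~valid, :] = np.nan

    traj = JointTrajectorySet(sampled.joint_names, pos, ts, params.rate_hz, valid)
    return TaskRecording(truth.participant_id, truth.task, system, traj,
                         truth.annotations)


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySet:
    """Paired recordings plus the ground-truth parameter table."""

    recordings: tuple[TaskRecording, ...]
    ground_truth: pd.DataFrame
    config: SyntheticConfig

    def pairs(self):
        """Yield (participant_id, task, reference recording, test recording)."""
        index = {(r.participant_id, r.task, r.system): r for r in self.recordings}
        seen = []
        for r in self.recordings:
            key = (r.participant_id, r.task)
            if key in seen:
                continue
            seen.append(key)
            ref = index.get((*key, "reference"))
            test = index.get((*key, "test"))
            if ref is not None and test is not None:
                yield (*key, ref, test)


def generate_study(config: SyntheticConfig) -> StudySet:
    """Generate the full virtual study: paired reference/test recordings for
    every participant x task, with annotations and ground-truth values."""
    ss = np.random.SeedSequence(config.seed)
    rng_statures = np.random.default_rng(ss.spawn(1)[0])
    lo, hi = config.stature_range_mm
    statures = rng_statures.uniform(lo, hi, config.n_participants)

    recordings: list[TaskRecording] = []
    truth_rows = []
    obs_seeds = ss.spawn(config.n_participants * len(config.tasks) * 2)
    k = 0
    for i, stature in enumerate(statures):
        pid = f"P{i + 1:02d}"
        skel = SkeletonModel(stature_mm=float(stature))
        for task in config.tasks:
            truth, gt = generate_task(skel, task, config.task_params, pid,
                                      config.internal_rate_hz)
            for system, obs in (("reference", config.reference), ("test", config.test)):
                rng = np.random.default_rng(obs_seeds[k])
                k += 1
                recordings.append(observe(truth, system, obs, rng))
            for name, value in gt.items():
                units = "deg" if "angle" in name else "mm"
                truth_rows.append({"participant": pid, "task": task,
                                   "parameter": name, "value": value,
                                   "units": units})
    gt_df = pd.DataFrame(truth_rows,
                         columns=["participant", "task", "parameter", "value", "units"])
    return StudySet(tuple(recordings), gt_df, config)
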