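"""Clinically motivated motion parameters from joint trajectories.

All angle parameters are scalar three-point angles computed directly from
joint positions (e.g. the elbow angle at the elbow vertex between the rays to
the shoulder and the wrist) — deliberately identical for every capture system
so that differences between systems reflect tracking, not angle conventions.
Displacements are expressed in body-referenced medio-lateral / vertical /
anterio-posterior components; speeds are finite-difference magnitudes. No
smoothing or filtering is applied anywhere. Invalid frames propagate: a
parameter is undefined wherever any input joint was unobserved.

Sign conventions
----------------
* reach distance: positive across the body midline (contralateral side);
* displacement components: positive along +ml (left), +vertical (up),
  +ap (forward);
* distances to planes: positive on the side of the plane normal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trajectories import JointTrajectorySet, ReferenceFrame, TaskRecording, _TIME_TOL

__all__ = [
    "ScalarSeries", "Plane", "PeakMeasure", "COM_WEIGHTS",
    "joint_angle_series", "trunk_rotation_series", "displacement_series",
    "midpoint_series", "speed_series", "com_trajectory",
    "estimate_ground_plane", "max_reach_distance", "max_trunk_angles",
    "jump_height",
]


@dataclass(frozen=True)
class ScalarSeries:
    """A scalar motion parameter per frame, with a validity mask.

    ``kind`` is one of ``angle`` (degrees), ``displacement_component`` (mm)
    or ``speed`` (mm/s); ``axis_label`` names the body axis for displacement
    components.
    """

    values: np.ndarray
    timestamps: np.ndarray
    kind: str
    valid: np.ndarray
    axis_label: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.timestamps, dtype=float)
        m = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "valid", m)
        if self.kind not in ("angle", "displacement_component", "speed"):
            raise ValueError(f"unknown series kind: {self.kind!r}")
        if v.shape != t.shape or v.shape != m.shape:
            raise ValueError("values, timestamps and valid must share one shape")
        ok = v[m]
        if self.kind == "angle" and ok.size and (ok.min() < -1e-9 or ok.max() > 180 + 1e-9):
            raise ValueError("angle values must lie in [0, 180] degrees")
        if self.kind == "speed" and ok.size and ok.min() < -1e-9:
            raise ValueError("speed values must be non-negative")

    @property
    def units(self) -> str:
        return {"angle": "deg", "displacement_component": "mm", "speed": "mm/s"}[self.kind]

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        return (self.timestamps >= t0 - _TIME_TOL) & (self.timestamps <= t1 + _TIME_TOL)


@dataclass(frozen=True)
class Plane:
    """A plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must have unit length")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal


@dataclass(frozen=True)
class PeakMeasure:
    """A single-number parameter: the extreme of a series inside a window."""

    name: str
    value: float
    frame_index: int
    window: tuple[float, float]
    units: str


#: Fixed per-joint weights used to derive a whole-body centre of mass for
#: systems that do not export one. Inspired by standard segment-mass tables
#: (head ~8%, trunk split between shoulder and hip markers, limbs the rest);
#: only relative geometry matters for the displacement parameters computed
#: from it. Weights sum to 1.
COM_WEIGHTS = {
    "head": 0.081,
    "shoulder_l": 0.120, "shoulder_r": 0.120,
    "hip_l": 0.1795, "hip_r": 0.1795,
    "elbow_l": 0.033, "elbow_r": 0.033,
    "wrist_l": 0.025, "wrist_r": 0.025,
    "knee_l": 0.070, "knee_r": 0.070,
    "ankle_l": 0.020, "ankle_r": 0.020,
    "foot_l": 0.012, "foot_r": 0.012,
}


def _angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle between row vectors u and v in degrees via atan2 (stable near 0/180)."""
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    dot = np.einsum("...i,...i->...", u, v)
    return np.degrees(np.arctan2(cross, dot))


def joint_angle_series(a, b, c, timestamps, valid) -> ScalarSeries:
    """Per-frame angle (deg) at vertex ``b`` between the rays b->a and b->c.

    ``a``, ``b``, ``c`` are ``(n, 3)`` point trajectories on a shared grid.
    Frames where either ray has zero length are marked invalid with a warning.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    valid = np.asarray(valid, dtype=bool).copy()
    u, v = a - b, c - b
    with np.errstate(invalid="ignore"):
        nu = np.linalg.norm(u, axis=-1)
        nv = np.linalg.norm(v, axis=-1)
    degenerate = valid & ((nu <= 1e-12) | (nv <= 1e-12))
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} frame(s) with zero-length ray marked invalid",
            stacklevel=2,
        )
        valid &= ~degenerate
    vals = np.full(len(valid), np.nan)
    vals[valid] = _angle_deg(u[valid], v[valid])
    return ScalarSeries(vals, timestamps, "angle", valid)


def trunk_rotation_series(hip_l, hip_r, shoulder_l, shoulder_r,
                          frame: ReferenceFrame, timestamps, valid) -> ScalarSeries:
    """Unsigned angle (deg) between the hip line and the shoulder line after
    projecting both onto the horizontal plane (orthogonal to vertical)."""
    valid = np.asarray(valid, dtype=bool).copy()
    hips = np.asarray(hip_l, float) - np.asarray(hip_r, float)
    shs = np.asarray(shoulder_l, float) - np.asarray(shoulder_r, float)
    vz = frame.vertical

    def project(d):
        return d - np.outer(d @ vz, vz)

    ph, ps = project(hips), project(shs)
    with np.errstate(invalid="ignore"):
        degenerate = valid & (
            (np.linalg.norm(ph, axis=-1) <= 1e-9) | (np.linalg.norm(ps, axis=-1) <= 1e-9)
        )
    valid &= ~degenerate
    vals = np.full(len(valid), np.nan)
    vals[valid] = _angle_deg(ph[valid], ps[valid])
    return ScalarSeries(vals, timestamps, "angle", valid)


def displacement_series(p, frame: ReferenceFrame, timestamps, valid,
                        baseline_window: tuple[float, float]):
    """3D displacement of point trajectory ``p`` relative to its mean position
    over ``baseline_window``, split into (medio-lateral, vertical,
    anterio-posterior) :class:`ScalarSeries` — returned in that order."""
    p = np.asarray(p, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    base_mask = valid & (timestamps >= baseline_window[0] - _TIME_TOL) \
        & (timestamps <= baseline_window[1] + _TIME_TOL)
    if not base_mask.any():
        raise ValueError("baseline window contains no valid frames")
    disp = p - p[base_mask].mean(axis=0)
    out = []
    for axis_vec, label in ((frame.ml, "medio-lateral"),
                            (frame.vertical, "vertical"),
                            (frame.ap, "anterio-posterior")):
        vals = np.where(valid, disp @ axis_vec, np.nan)
        out.append(ScalarSeries(vals, timestamps, "displacement_component",
                                valid, axis_label=label))
    return tuple(out)


def midpoint_series(p, q) -> np.ndarray:
    """Frame-wise arithmetic midpoint of two point trajectories."""
    return 0.5 * (np.asarray(p, dtype=float) + np.asarray(q, dtype=float))


def com_trajectory(traj: JointTrajectorySet) -> np.ndarray:
    """Centre-of-mass trajectory: the recorded ``com`` joint when present,
    otherwise the fixed-weight joint average of :data:`COM_WEIGHTS`."""
    if traj.has_joint("com"):
        return traj.joint("com")
    missing = [j for j in COM_WEIGHTS if not traj.has_joint(j)]
    if missing:
        raise ValueError(f"cannot derive centre of mass; missing joints: {missing}")
    com = np.zeros((traj.n_frames, 3))
    for j, w in COM_WEIGHTS.items():
        com += w * traj.joint(j)
    return com


def speed_series(p, timestamps, valid) -> ScalarSeries:
    """Finite-difference speed (mm/s) of a point trajectory.

    Central differences on interior valid frames, one-sided at the ends of
    the series; frames bordering an interior invalid gap are themselves
    marked invalid (their derivative would straddle unobserved data).
    """
    p = np.asarray(p, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n = len(t)
    if valid.sum() < 3:
        raise ValueError("speed requires at least 3 valid frames")
    vals = np.full(n, np.nan)
    out_valid = np.zeros(n, dtype=bool)
    # runs of consecutive valid frames
    idx = np.flatnonzero(valid)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        if len(run) < 2:
            continue
        tp, pp = t[run], p[run]
        vel = np.gradient(pp, tp, axis=0)  # central interior, one-sided ends
        vals[run] = np.linalg.norm(vel, axis=-1)
        out_valid[run] = True
    # frames adjacent to an invalid frame are invalid
    inner_bad = ~valid
    neighbour_bad = np.zeros(n, dtype=bool)
    neighbour_bad[1:] |= inner_bad[:-1]
    neighbour_bad[:-1] |= inner_bad[1:]
    out_valid &= ~neighbour_bad
    vals[~out_valid] = np.nan
    return ScalarSeries(vals, t, "speed", out_valid)


def estimate_ground_plane(recording: TaskRecording,
                          standing_window: tuple[float, float],
                          foot_height_mm: float = 0.0) -> Plane:
    """Least-squares plane through the foot-joint positions of the standing
    window, offset downward by ``foot_height_mm``; normal oriented toward the
    head side (up, for an upright participant)."""
    traj = recording.trajectories
    mask = traj.valid & traj.window_mask(*standing_window)
    pts = np.concatenate([traj.joint("foot_l")[mask], traj.joint("foot_r")[mask]])
    if pts.shape[0] < 3:
        raise ValueError("standing window must contain at least 3 valid foot frames")
    centroid = pts.mean(axis=0)
    sv = np.linalg.svd(pts - centroid, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("foot points are collinear; plane is not determined")
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    head_mean = traj.joint("head")[mask].mean(axis=0)
    if np.dot(normal, head_mean - centroid) < 0:
        normal = -normal
    return Plane(centroid - foot_height_mm * normal, normal)


def _peak(values, valid, timestamps, window, mode="max"):
    mask = valid & (np.asarray(timestamps) >= window[0] - _TIME_TOL) \
        & (np.asarray(timestamps) <= window[1] + _TIME_TOL)
    if not mask.any():
        raise ValueError("no valid frames in window")
    cand = np.where(mask, values, -np.inf if mode == "max" else np.inf)
    idx = int(np.argmax(cand) if mode == "max" else np.argmin(cand))  # ties: earliest
    return float(values[idx]), idx


def max_reach_distance(wrist, shoulder_l, shoulder_r, frame: ReferenceFrame,
                       timestamps, valid,
                       start_window: tuple[float, float],
                       movement_window: tuple[float, float],
                       side: str) -> PeakMeasure:
    """Maximum signed wrist excursion (mm) beyond the sagittal plane.

    The sagittal plane contains the vertical and anterio-posterior axes and
    passes through the mid-shoulder point averaged over ``start_window``.
    ``side`` names the reaching arm; positive distance is across the body
    midline (contralateral side).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if start_window[1] > movement_window[0] + _TIME_TOL:
        raise ValueError("start window must precede movement window")
    timestamps = np.asarray(timestamps, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    base = valid & (timestamps >= start_window[0] - _TIME_TOL) \
        & (timestamps <= start_window[1] + _TIME_TOL)
    if not base.any():
        raise ValueError("start window contains no valid frames")
    mid_sh = midpoint_series(shoulder_l, shoulder_r)[base].mean(axis=0)
    # +ml points left: crossing the midline is +ml for the right arm
    normal = frame.ml if side == "right" else -frame.ml
    plane = Plane(mid_sh, normal)
    dist = plane.signed_distance(np.asarray(wrist, dtype=float))
    value, idx = _peak(dist, valid, timestamps, movement_window, "max")
    return PeakMeasure("max_reach_distance", value, idx, movement_window, "mm")


def max_trunk_angles(shoulder_l, shoulder_r, hip_l, hip_r, frame: ReferenceFrame,
                     timestamps, valid,
                     movement_windows: dict[str, tuple[float, float]]
                     ) -> dict[str, PeakMeasure]:
    """Maximum trunk inclination (deg) per bending direction.

    The trunk axis runs from mid-hip to mid-shoulder. Lateral (left/right)
    angles are measured between vertical and the axis projected onto the
    frontal plane; ventral/dorsal use the projection onto the sagittal plane.
    ``movement_windows`` maps direction names (left, right, ventral, dorsal)
    to annotation intervals; the maximum unsigned angle is taken per window.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    axis = midpoint_series(shoulder_l, shoulder_r) - midpoint_series(hip_l, hip_r)
    with np.errstate(invalid="ignore"):
        degenerate = valid & (np.linalg.norm(axis, axis=-1) <= 1e-9)
    valid = valid & ~degenerate
    out = {}
    for direction, window in movement_windows.items():
        if direction in ("left", "right"):
            drop = frame.ap     # frontal plane spans ml + vertical
        elif direction in ("ventral", "dorsal"):
            drop = frame.ml     # sagittal plane spans ap + vertical
        else:
            raise ValueError(f"unknown bending direction: {direction!r}")
        proj = axis - np.outer(axis @ drop, drop)
        ok = valid & (np.linalg.norm(proj, axis=-1) > 1e-9)
        ang = np.full(len(timestamps), np.nan)
        ang[ok] = _angle_deg(proj[ok], np.broadcast_to(frame.vertical, proj[ok].shape))
        value, idx = _peak(ang, ok, timestamps, window, "max")
        out[direction] = PeakMeasure(f"trunk_angle_{direction}", value, idx, window, "deg")
    return out


def jump_height(ankle_l, ankle_r, ground: Plane, timestamps, valid,
                movement_window: tuple[float, float]) -> PeakMeasure:
    """Overall maximum perpendicular ankle-to-ground distance (mm) over both
    ankles and all valid frames of the movement window."""
    timestamps = np.asarray(timestamps, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    d_l = ground.signed_distance(np.asarray(ankle_l, dtype=float))
    d_r = ground.signed_distance(np.asarray(ankle_r, dtype=float))
    with np.errstate(invalid="ignore"):
        best = np.where(np.nan_to_num(d_l, nan=-np.inf) >= np.nan_to_num(d_r, nan=-np.inf),
                        d_l, d_r)
    value, idx = _peak(best, valid, timestamps, movement_window, "max")
    return PeakMeasure("jump_height", value, idx, movement_window, "mm")
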