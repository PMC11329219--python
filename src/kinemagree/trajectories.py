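"""Joint-trajectory containers, file I/O, resampling and rigid alignment.

The central container is :class:`JointTrajectorySet`: time-stamped 3D positions
(millimetres) for a canonical set of body joints from one capture system, with a
per-frame validity mask ("body detected" vs. not). Recordings from two systems
are compared after (a) rigid alignment into a common, gravity-aligned world
frame and (b) resampling onto a common timestamp grid. Invalid frames are
masked, never interpolated over, for downstream parameter computation.

Units are millimetres and seconds throughout; conversions happen only at the
I/O boundary (e.g. metre-unit TRC files).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical joint set. ``com`` (whole-body centre of mass) is optional —
#: systems that do not export it directly can derive it (see
#: :func:`kinemagree.parameters.com_trajectory`).
CANONICAL_JOINTS = (
    "head",
    "shoulder_l", "shoulder_r",
    "elbow_l", "elbow_r",
    "wrist_l", "wrist_r",
    "hip_l", "hip_r",
    "knee_l", "knee_r",
    "ankle_l", "ankle_r",
    "foot_l", "foot_r",
    "com",
)

TASKS = ("reach", "trunk_bending", "sslr", "squat", "jumping_jacks")
SYSTEMS = ("reference", "test", "truth")

_TIME_TOL = 1e-9  # seconds; tolerance for "same timestamp" comparisons


@dataclass(frozen=True)
class JointTrajectorySet:
    """3D joint positions over time from a single capture system.

    Parameters
    ----------
    joint_names
        Ordered subset of :data:`CANONICAL_JOINTS`.
    positions
        Array of shape ``(n_joints, n_frames, 3)``, millimetres.
    timestamps
        Strictly increasing, seconds from recording start, ``(n_frames,)``.
    rate
        Nominal sampling frequency in Hz.
    valid
        Boolean per-frame mask; ``False`` marks frames on which the system
        did not observe the body. Positions must be finite on valid frames.
    """

    joint_names: tuple[str, ...]
    positions: np.ndarray
    timestamps: np.ndarray
    rate: float
    valid: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "joint_names", tuple(self.joint_names))
        pos = np.asarray(self.positions, dtype=float)
        ts = np.asarray(self.timestamps, dtype=float)
        val = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "valid", val)
        for name in self.joint_names:
            if name not in CANONICAL_JOINTS:
                raise ValueError(f"unknown joint label: {name!r}")
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise ValueError("positions must have shape (n_joints, n_frames, 3)")
        if pos.shape[0] != len(self.joint_names):
            raise ValueError("positions first axis must match joint_names")
        n = pos.shape[1]
        if ts.shape != (n,):
            raise ValueError("timestamps length must equal frame count")
        if val.shape != (n,):
            raise ValueError("valid mask length must equal frame count")
        if n > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if val.any() and not np.all(np.isfinite(pos[:, val, :])):
            raise ValueError("positions must be finite on valid frames")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def has_joint(self, name: str) -> bool:
        return name in self.joint_names

    def joint(self, name: str) -> np.ndarray:
        """Positions of one joint, shape ``(n_frames, 3)``."""
        try:
            i = self.joint_names.index(name)
        except ValueError:
            raise KeyError(f"joint {name!r} not present") from None
        return self.positions[i]

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of frames whose timestamp lies in ``[t0, t1]``."""
        return (self.timestamps >= t0 - _TIME_TOL) & (self.timestamps <= t1 + _TIME_TOL)

    def with_positions(self, positions: np.ndarray) -> "JointTrajectorySet":
        return replace(self, positions=positions)


@dataclass(frozen=True)
class Annotations:
    """Task annotations: movement start/end and repetition boundaries (s)."""

    start: float
    end: float
    reps: tuple[float, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "reps", tuple(float(r) for r in self.reps))
        if self.end <= self.start:
            raise ValueError("annotation end must follow start")
        if len(self.reps) > 1 and not np.all(np.diff(self.reps) > 0):
            raise ValueError("repetition boundaries must be strictly increasing")
        for r in self.reps:
            if not (self.start < r < self.end):
                raise ValueError("repetition boundaries must lie inside [start, end]")

    def segments(self) -> list[tuple[float, float]]:
        """Consecutive windows delimited by start, repetition boundaries, end."""
        edges = (self.start, *self.reps, self.end)
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


@dataclass(frozen=True)
class TaskRecording:
    """One participant x task x system recording with annotations."""

    participant_id: str
    task: str
    system: str
    trajectories: JointTrajectorySet
    annotations: Annotations

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task: {self.task!r}")
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system: {self.system!r}")
        ts = self.trajectories.timestamps
        lo, hi = ts[0] - _TIME_TOL, ts[-1] + _TIME_TOL
        for t in (self.annotations.start, self.annotations.end, *self.annotations.reps):
            if not (lo <= t <= hi):
                raise ValueError("annotation times must lie within the recording span")


@dataclass(frozen=True)
class ReferenceFrame:
    """Body-referenced orthonormal frame: medio-lateral / anterio-posterior /
    vertical axes plus an origin (mean mid-hip of the standing window)."""

    origin: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    vertical: np.ndarray

    def __post_init__(self):
        for name in ("origin", "ml", "ap", "vertical"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        axes = np.stack([self.ml, self.ap, self.vertical])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise ValueError("axes must be orthonormal")
        if not np.allclose(np.cross(self.ml, self.ap), self.vertical, atol=1e-9):
            raise ValueError("axes must form a right-handed triad (ml x ap = vertical)")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R @ p + t`` (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an array of points with last axis 3 (any leading shape)."""
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_COL_RE = re.compile(r"^(?P<joint>.+)_(?P<axis>[xyz])$", re.IGNORECASE)


def _canonical(label: str) -> str:
    name = label.strip().lower()
    if name not in CANONICAL_JOINTS:
        raise ValueError(f"unknown joint label: {label!r}")
    return name


def read_trajectories(path, dialect: str = "csv_wide") -> JointTrajectorySet:
    """Read a joint trajectory file.

    ``csv_wide``: one row per frame, a ``time`` column plus ``<joint>_{x,y,z}``
    columns (case-insensitive canonical joint names). Frames with any missing
    coordinate are marked invalid, not dropped. ``trc``: marker-trajectory
    text format (read-only; markers must carry canonical joint names).
    """
    if dialect == "csv_wide":
        return _read_csv_wide(path)
    if dialect == "trc":
        return _read_trc(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_csv_wide(path) -> JointTrajectorySet:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if "time" not in cols:
        raise ValueError("csv_wide file must have a 'time' column")
    per_joint: dict[str, dict[str, str]] = {}
    for c in cols:
        if c == "time":
            continue
        m = _COL_RE.match(c)
        if m is None:
            raise ValueError(f"unrecognized column: {c!r}")
        joint = _canonical(m.group("joint"))
        per_joint.setdefault(joint, {})[m.group("axis").lower()] = c
    joints = [j for j in CANONICAL_JOINTS if j in per_joint]
    if not joints:
        raise ValueError("no joint columns found")
    for j in joints:
        if set(per_joint[j]) != {"x", "y", "z"}:
            raise ValueError(f"joint {j!r} must have x, y and z columns")
    ts = df["time"].to_numpy(dtype=float)
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise ValueError("timestamps must be strictly increasing")
    pos = np.empty((len(joints), len(ts), 3))
    for i, j in enumerate(joints):
        for k, axis in enumerate("xyz"):
            pos[i, :, k] = df[per_joint[j][axis]].to_numpy(dtype=float)
    valid = np.all(np.isfinite(pos), axis=(0, 2))
    rate = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 1.0
    return JointTrajectorySet(tuple(joints), pos, ts, rate, valid)


def _read_trc(path) -> JointTrajectorySet:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise ValueError("truncated TRC file")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    rate = float(meta.get("DataRate", 0) or 0)
    units = meta.get("Units", "mm").strip().lower()
    scale = {"mm": 1.0, "m": 1000.0, "cm": 10.0}.get(units)
    if scale is None:
        raise ValueError(f"unsupported TRC units: {units!r}")
    header = lines[3].split("\t")
    markers = [_canonical(h) for h in header[2:] if h.strip()]
    data_rows = [ln.split("\t") for ln in lines[5:] if ln.strip()]
    n = len(data_rows)
    ts = np.empty(n)
    pos = np.full((len(markers), n, 3), np.nan)
    for r, row in enumerate(data_rows):
        ts[r] = float(row[1])
        for m in range(len(markers)):
            for k in range(3):
                cell = row[2 + 3 * m + k] if 2 + 3 * m + k < len(row) else ""
                if cell.strip():
                    pos[m, r, k] = float(cell) * scale
    if n > 1 and not np.all(np.diff(ts) > 0):
        raise ValueError("timestamps must be strictly increasing")
    order = [j for j in CANONICAL_JOINTS if j in markers]
    pos = pos[[markers.index(j) for j in order]]
    valid = np.all(np.isfinite(pos), axis=(0, 2))
    if rate <= 0:
        rate = 1.0 / float(np.median(np.diff(ts))) if n > 1 else 1.0
    return JointTrajectorySet(tuple(order), pos, ts, rate, valid)


def write_trajectories(traj: JointTrajectorySet, path) -> None:
    """Write the wide-CSV dialect (the only writer; see module docstring).

    Coordinates on invalid frames are written as empty cells, so validity
    round-trips through the any-missing-coordinate rule of the reader.
    """
    data = {"time": traj.timestamps}
    for i, j in enumerate(traj.joint_names):
        coords = traj.positions[i].copy()
        coords[~traj.valid] = np.nan
        for k, axis in enumerate("xyz"):
            data[f"{j}_{axis}"] = coords[:, k]
    # %.17g guarantees float64 values survive the text round trip exactly
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to(traj: JointTrajectorySet, target_timestamps) -> JointTrajectorySet:
    """Resample onto ``target_timestamps`` by per-axis linear interpolation.

    Interpolation bridges across invalid frames (between the nearest valid
    frames), but a target frame is reported valid only when both bracketing
    *source* frames are valid — i.e. only where the source stream actually
    observed the interval. No extrapolation: targets outside the source span
    raise ``ValueError``.
    """
    tt = np.asarray(target_timestamps, dtype=float)
    ts = traj.timestamps
    if tt.size and (tt.min() < ts[0] - _TIME_TOL or tt.max() > ts[-1] + _TIME_TOL):
        raise ValueError("target timestamps outside source time span")
    tt_c = np.clip(tt, ts[0], ts[-1])

    # validity: exact hits inherit the hit frame's validity, interior targets
    # require both immediate bracketing source frames valid
    right = np.searchsorted(ts, tt_c, side="left")
    right = np.clip(right, 0, len(ts) - 1)
    exact = np.abs(ts[right] - tt_c) <= _TIME_TOL
    left = np.clip(right - 1, 0, len(ts) - 1)
    valid = np.where(exact, traj.valid[right], traj.valid[left] & traj.valid[right])

    src_valid = traj.valid
    pos = np.full((len(traj.joint_names), tt.size, 3), np.nan)
    if src_valid.sum() >= 1:
        tv = ts[src_valid]
        for i in range(len(traj.joint_names)):
            for k in range(3):
                pos[i, :, k] = np.interp(tt_c, tv, traj.positions[i, src_valid, k])
    pos[:, ~valid, :] = np.nan
    rate = 1.0 / float(np.median(np.diff(tt))) if tt.size > 1 else traj.rate
    return JointTrajectorySet(traj.joint_names, pos, tt, rate, valid)


# ---------------------------------------------------------------------------
# Rigid alignment (Kabsch) and reference-frame construction
# ---------------------------------------------------------------------------

def estimate_rigid_transform(src_points, dst_points) -> RigidTransform:
    """Least-squares rigid transform mapping ``src_points`` onto ``dst_points``.

    Kabsch algorithm: the returned proper rotation + translation minimise the
    mean squared correspondence distance (no scaling; reflections excluded).
    Requires at least three non-collinear correspondences.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    if src.shape[0] < 3:
        raise ValueError("need at least 3 point correspondences")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    a, b = src - cs, dst - cd
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("source points are collinear; rotation is not determined")
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    return RigidTransform(rot, cd - rot @ cs)


def build_reference_frame(
    traj: JointTrajectorySet,
    standing_window: tuple[float, float],
    gravity,
) -> ReferenceFrame:
    """Body axes from a standing window and the gravity direction.

    ``gravity`` points down; the stored vertical axis opposes it. The
    medio-lateral axis is the mean right-to-left shoulder-line direction over
    the window, orthogonalised against vertical; anterio-posterior completes
    the right-handed triad (``ml x ap = vertical``). Origin is the mean
    mid-hip position.
    """
    g = np.asarray(gravity, dtype=float)
    vertical = -g / np.linalg.norm(g)
    mask = traj.valid & traj.window_mask(*standing_window)
    if not mask.any():
        raise ValueError("standing window contains no valid frames")
    sh = traj.joint("shoulder_l")[mask] - traj.joint("shoulder_r")[mask]
    ml_raw = sh.mean(axis=0)
    ml = ml_raw - np.dot(ml_raw, vertical) * vertical
    norm = np.linalg.norm(ml)
    if norm <= 1e-6 * max(np.linalg.norm(ml_raw), 1.0):
        raise ValueError("shoulder line is parallel to gravity in the standing window")
    ml /= norm
    ap = np.cross(vertical, ml)
    mid_hip = 0.5 * (traj.joint("hip_l")[mask] + traj.joint("hip_r")[mask])
    return ReferenceFrame(mid_hip.mean(axis=0), ml, ap, vertical)
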