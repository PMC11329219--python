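"""Orchestration of the full virtual validation study.

``run_study`` takes paired recordings (synthetic or loaded from disk), aligns
the test stream rigidly into the reference system's world frame, extracts
every parameter mapped to each task, and aggregates between-system agreement
into two tables mirroring how concurrent-validity studies report:

* table 1 — time-series parameters: per-participant Pearson r and MAE,
  averaged (mean, SD) across participants;
* table 2 — peak and smoothness parameters: per-method means, MAE,
  Bland-Altman bias, limits of agreement and paired t-test p-value.

Conventions (documented design choices):

* the reference system's world frame is taken as floor-calibrated, so gravity
  is its -z axis; the body reference frame and the ground plane are built
  from the reference recording's standing window and shared by both systems;
* the reference stream is resampled onto the test stream's timestamps for
  time-series comparison (downsampling the clean stream rather than
  fabricating high-frequency content in the noisy one); peaks and smoothness
  are computed per system on its own grid;
* differences are oriented test - reference;
* recordings or parameters that fail a precondition (e.g. dropout inside a
  smoothness window) are excluded and logged, never silently dropped.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import parameters as par
from .smoothness import SparcParams, segment_and_average, sparc
from .synthetic import StudySet, SyntheticConfig, generate_study
from .trajectories import (
    Annotations, JointTrajectorySet, TaskRecording, build_reference_frame,
    estimate_rigid_transform, read_trajectories, resample_to, write_trajectories,
)

log = logging.getLogger("kinemagree")

GRAVITY_WORLD = np.array([0.0, 0.0, -1.0])  # reference world is floor-calibrated

#: parameter -> units for everything the pipeline emits
PARAM_UNITS = {
    "trunk_rotation": "deg", "elbow_angle": "deg", "knee_angle": "deg",
    "ankle_angle": "deg", "hip_angle": "deg",
    "upper_trunk_displacement_ml": "mm", "upper_trunk_displacement_v": "mm",
    "upper_trunk_displacement_ap": "mm",
    "com_displacement_ml": "mm", "com_displacement_v": "mm",
    "com_displacement_ap": "mm",
    "wrist_speed": "mm/s", "ankle_speed": "mm/s",
    "max_reach_distance": "mm", "jump_height": "mm",
    "trunk_angle_left": "deg", "trunk_angle_right": "deg",
    "trunk_angle_ventral": "deg", "trunk_angle_dorsal": "deg",
    "knee_angle_peak_flexion": "deg",
    "sparc": "-",
}

#: task -> time-series parameter names
TASK_TIMESERIES = {
    "reach": ("trunk_rotation", "elbow_angle"),
    "trunk_bending": (),
    "sslr": ("hip_angle", "com_displacement_ml", "com_displacement_v",
             "com_displacement_ap"),
    "squat": ("knee_angle", "ankle_angle", "upper_trunk_displacement_ml",
              "upper_trunk_displacement_v", "upper_trunk_displacement_ap"),
    "jumping_jacks": ("wrist_speed", "ankle_speed"),
}

#: task -> scalar (peak / smoothness) parameter names; smoothness is computed
#: for all tasks except the squat
TASK_SCALARS = {
    "reach": ("max_reach_distance", "sparc"),
    "trunk_bending": ("trunk_angle_left", "trunk_angle_right",
                      "trunk_angle_ventral", "trunk_angle_dorsal", "sparc"),
    "sslr": ("sparc",),
    "squat": ("knee_angle_peak_flexion",),
    "jumping_jacks": ("jump_height", "sparc"),
}

#: joint whose speed profile feeds SPARC, per task
SPARC_JOINT = {
    "reach": "wrist_r",
    "trunk_bending": None,      # mid-shoulder midpoint
    "sslr": "ankle_r",
    "jumping_jacks": "wrist_r",
}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one pipeline run (synthetic or file input)."""

    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    tasks: tuple[str, ...] | None = None
    sparc: SparcParams = field(default_factory=SparcParams)
    plots: bool = False

    def __post_init__(self):
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("exactly one of synthetic / input_dir must be set")
        if self.tasks is not None:
            object.__setattr__(self, "tasks", tuple(self.tasks))

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = {"input_dir": self.input_dir,
             "tasks": list(self.tasks) if self.tasks else None,
             "sparc": asdict(self.sparc), "plots": self.plots,
             "synthetic": asdict(self.synthetic) if self.synthetic else None}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        from kinemagree.synthetic import ObservationParams, TaskParams
        syn = d.get("synthetic")
        if syn is not None:
            syn = dict(syn)
            for key, klass in (("task_params", TaskParams),
                               ("reference", ObservationParams),
                               ("test", ObservationParams)):
                if key in syn and isinstance(syn[key], dict):
                    sub = dict(syn[key])
                    for k, v in sub.items():
                        if isinstance(v, list):
                            sub[k] = tuple(v)
                    syn[key] = klass(**sub)
            for k, v in syn.items():
                if isinstance(v, list):
                    syn[k] = tuple(v)
            syn = SyntheticConfig(**syn)
        sp = d.get("sparc")
        sparc_params = SparcParams(**sp) if isinstance(sp, dict) else SparcParams()
        return cls(synthetic=syn, input_dir=d.get("input_dir"),
                   tasks=tuple(d["tasks"]) if d.get("tasks") else None,
                   sparc=sparc_params, plots=bool(d.get("plots", False)))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class StudyReport:
    """Aggregated study output: agreement tables, per-recording values, and
    the exclusion log (which, together with the retained rows, accounts for
    every generated/loaded recording pair)."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    values: pd.DataFrame
    timeseries: pd.DataFrame
    exclusions: pd.DataFrame
    pair_status: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(outdir / "table1_timeseries.csv", index=False)
        self.table2.to_csv(outdir / "table2_peaks_smoothness.csv", index=False)
        self.values.to_csv(outdir / "parameter_values.csv", index=False)
        self.timeseries.to_csv(outdir / "timeseries_agreement.csv", index=False)
        self.exclusions.to_csv(outdir / "exclusions.csv", index=False)
        self.pair_status.to_csv(outdir / "pair_status.csv", index=False)


# ---------------------------------------------------------------------------
# Per-recording extraction
# ---------------------------------------------------------------------------

def _standing_window(rec: TaskRecording) -> tuple[float, float]:
    return (float(rec.trajectories.timestamps[0]), rec.annotations.start)


def _frame_and_ground(ref: TaskRecording):
    """Body frame and ground plane from the reference recording's standing
    window; the ground plane sits at the mean foot height with the calibrated
    vertical as its normal."""
    standing = _standing_window(ref)
    frame = build_reference_frame(ref.trajectories, standing, GRAVITY_WORLD)
    traj = ref.trajectories
    mask = traj.valid & traj.window_mask(*standing)
    feet = np.concatenate([traj.joint("foot_l")[mask], traj.joint("foot_r")[mask]])
    ground = par.Plane(feet.mean(axis=0), frame.vertical)
    return frame, ground


def _timeseries_series(rec: TaskRecording, frame) -> dict[str, par.ScalarSeries]:
    """All time-series parameters of the recording's task, full length."""
    traj = rec.trajectories
    t, v = traj.timestamps, traj.valid
    ann = rec.annotations
    baseline = _standing_window(rec)
    out: dict[str, par.ScalarSeries] = {}
    task = rec.task
    if task == "reach":
        out["trunk_rotation"] = par.trunk_rotation_series(
            traj.joint("hip_l"), traj.joint("hip_r"),
            traj.joint("shoulder_l"), traj.joint("shoulder_r"), frame, t, v)
        out["elbow_angle"] = par.joint_angle_series(
            traj.joint("shoulder_r"), traj.joint("elbow_r"), traj.joint("wrist_r"), t, v)
    elif task == "squat":
        out["knee_angle"] = par.joint_angle_series(
            traj.joint("hip_r"), traj.joint("knee_r"), traj.joint("ankle_r"), t, v)
        out["ankle_angle"] = par.joint_angle_series(
            traj.joint("knee_r"), traj.joint("ankle_r"), traj.joint("foot_r"), t, v)
        mid_sh = par.midpoint_series(traj.joint("shoulder_l"), traj.joint("shoulder_r"))
        ml, vert, ap = par.displacement_series(mid_sh, frame, t, v, baseline)
        out["upper_trunk_displacement_ml"] = ml
        out["upper_trunk_displacement_v"] = vert
        out["upper_trunk_displacement_ap"] = ap
    elif task == "sslr":
        out["hip_angle"] = par.joint_angle_series(
            traj.joint("shoulder_r"), traj.joint("hip_r"), traj.joint("knee_r"), t, v)
        com = par.com_trajectory(traj)
        ml, vert, ap = par.displacement_series(com, frame, t, v, baseline)
        out["com_displacement_ml"] = ml
        out["com_displacement_v"] = vert
        out["com_displacement_ap"] = ap
    elif task == "jumping_jacks":
        out["wrist_speed"] = par.speed_series(traj.joint("wrist_r"), t, v)
        out["ankle_speed"] = par.speed_series(traj.joint("ankle_r"), t, v)
    _ = ann
    return out


def _sparc_value(rec: TaskRecording, sparc_params: SparcParams) -> float:
    """SPARC of the task's characteristic speed profile over the movement
    window (per-repetition average for the rhythmic jumping jacks)."""
    traj = rec.trajectories
    joint = SPARC_JOINT[rec.task]
    if joint is None:
        p = par.midpoint_series(traj.joint("shoulder_l"), traj.joint("shoulder_r"))
    else:
        p = traj.joint(joint)
    speed = par.speed_series(p, traj.timestamps, traj.valid)
    ann = rec.annotations
    mask = speed.window_mask(ann.start, ann.end)
    windowed = par.ScalarSeries(speed.values[mask], speed.timestamps[mask],
                                "speed", speed.valid[mask])
    if rec.task == "jumping_jacks":
        return segment_and_average(windowed, ann.reps, sparc_params).mean_of_repetitions
    return sparc(windowed, sparc_params).sparc


def _scalar_values(rec: TaskRecording, frame, ground,
                   sparc_params: SparcParams):
    """Peak and smoothness scalars for one recording. Returns
    (values dict, list of (parameter, reason) exclusions)."""
    traj = rec.trajectories
    t, v = traj.timestamps, traj.valid
    ann = rec.annotations
    window = (ann.start, ann.end)
    values: dict[str, float] = {}
    dropped: list[tuple[str, str]] = []
    task = rec.task

    def attempt(name, fn):
        try:
            values[name] = float(fn())
        except (ValueError, KeyError) as exc:
            dropped.append((name, str(exc)))

    if task == "reach":
        attempt("max_reach_distance", lambda: par.max_reach_distance(
            traj.joint("wrist_r"), traj.joint("shoulder_l"), traj.joint("shoulder_r"),
            frame, t, v, _standing_window(rec), window, side="right").value)
    elif task == "trunk_bending":
        segs = rec.annotations.segments()
        if len(segs) == 4:
            windows = dict(zip(("left", "right", "ventral", "dorsal"), segs))

            def trunk():
                return par.max_trunk_angles(
                    traj.joint("shoulder_l"), traj.joint("shoulder_r"),
                    traj.joint("hip_l"), traj.joint("hip_r"), frame, t, v, windows)
            try:
                for direction, peak in trunk().items():
                    values[f"trunk_angle_{direction}"] = peak.value
            except ValueError as exc:
                for d in windows:
                    dropped.append((f"trunk_angle_{d}", str(exc)))
        else:
            for d in ("left", "right", "ventral", "dorsal"):
                dropped.append((f"trunk_angle_{d}",
                                "trunk bending requires 4 annotated segments"))
    elif task == "squat":
        def peak_flexion():
            series = par.joint_angle_series(
                traj.joint("hip_r"), traj.joint("knee_r"), traj.joint("ankle_r"), t, v)
            mask = series.valid & series.window_mask(*window)
            if not mask.any():
                raise ValueError("no valid knee-angle frames in window")
            return float(np.min(series.values[mask]))
        attempt("knee_angle_peak_flexion", peak_flexion)
    elif task == "jumping_jacks":
        attempt("jump_height", lambda: par.jump_height(
            traj.joint("ankle_l"), traj.joint("ankle_r"), ground, t, v, window).value)

    if "sparc" in TASK_SCALARS[task]:
        attempt("sparc", lambda: _sparc_value(rec, sparc_params))
    return values, dropped


# ---------------------------------------------------------------------------
# Pair processing and aggregation
# ---------------------------------------------------------------------------

def _align_test_to_reference(ref: TaskRecording, test: TaskRecording) -> TaskRecording:
    """Rigidly align the test recording into the reference world frame using
    mean joint positions over the shared standing window."""
    standing = _standing_window(ref)
    src_pts, dst_pts = [], []
    for j in test.trajectories.joint_names:
        if not ref.trajectories.has_joint(j):
            continue
        m_t = test.trajectories.valid & test.trajectories.window_mask(*standing)
        m_r = ref.trajectories.valid & ref.trajectories.window_mask(*standing)
        if not (m_t.any() and m_r.any()):
            continue
        src_pts.append(test.trajectories.joint(j)[m_t].mean(axis=0))
        dst_pts.append(ref.trajectories.joint(j)[m_r].mean(axis=0))
    if len(src_pts) < 3:
        raise ValueError("not enough valid standing-window joints for alignment")
    transform = estimate_rigid_transform(np.array(src_pts), np.array(dst_pts))
    aligned = test.trajectories.with_positions(
        transform.apply(test.trajectories.positions))
    return TaskRecording(test.participant_id, test.task, test.system,
                         aligned, test.annotations)


def _trim_to_span(rec: TaskRecording, t0: float, t1: float) -> TaskRecording:
    ts = rec.trajectories.timestamps
    keep = (ts >= t0 - 1e-9) & (ts <= t1 + 1e-9)
    if keep.all():
        return rec
    traj = rec.trajectories
    trimmed = JointTrajectorySet(traj.joint_names, traj.positions[:, keep],
                                 ts[keep], traj.rate, traj.valid[keep])
    return TaskRecording(rec.participant_id, rec.task, rec.system, trimmed,
                         rec.annotations)


def _process_pair(ref: TaskRecording, test: TaskRecording,
                  sparc_params: SparcParams):
    """Extract everything for one participant x task pair."""
    ts_rows, value_rows, exclusion_rows = [], [], []
    pid, task = ref.participant_id, ref.task

    def exclude(system, parameter, reason):
        exclusion_rows.append({"participant": pid, "task": task, "system": system,
                               "parameter": parameter, "reason": reason})

    test = _align_test_to_reference(ref, test)
    frame, ground = _frame_and_ground(ref)

    # --- time series on the common (test) grid -----------------------------
    ref_span = (ref.trajectories.timestamps[0], ref.trajectories.timestamps[-1])
    test_common = _trim_to_span(test, *ref_span)
    ref_common = TaskRecording(pid, task, "reference",
                               resample_to(ref.trajectories,
                                           test_common.trajectories.timestamps),
                               ref.annotations)
    ann = ref.annotations
    try:
        series_ref = _timeseries_series(ref_common, frame)
        series_test = _timeseries_series(test_common, frame)
    except ValueError as exc:
        series_ref, series_test = {}, {}
        for name in TASK_TIMESERIES[task]:
            exclude("both", name, str(exc))
    for name in series_ref:
        sr, st = series_ref[name], series_test[name]
        mask = sr.valid & st.valid & sr.window_mask(ann.start, ann.end)
        pair = agr.PairedSeries(st.values[mask], sr.values[mask], pid, name)
        try:
            r = agr.pearson_r(pair)
        except ValueError as exc:
            exclude("both", name, str(exc))
            continue
        mae = float(np.mean(np.abs(pair.x - pair.y)))
        ts_rows.append({"participant": pid, "task": task, "parameter": name,
                        "r": r, "mae": mae, "n_frames": int(mask.sum()),
                        "units": PARAM_UNITS[name]})

    # --- scalars per system on each system's own grid ----------------------
    for rec in (ref, test):
        vals, dropped = _scalar_values(rec, frame, ground, sparc_params)
        for name, value in vals.items():
            value_rows.append({"participant": pid, "task": task,
                               "system": rec.system, "parameter": name,
                               "value": value, "units": PARAM_UNITS[name]})
        for name, reason in dropped:
            exclude(rec.system, name, reason)
    return ts_rows, value_rows, exclusion_rows


def run_study(config: StudyConfig, outdir=None) -> StudyReport:
    """Run the full pipeline and aggregate the agreement tables.

    Deterministic given the config (and its synthetic seed). If ``outdir`` is
    given, all tables, the fully resolved config, and (optionally) plots are
    written there.
    """
    if config.synthetic is not None:
        syn = config.synthetic
        if config.tasks is not None:
            import dataclasses
            syn = dataclasses.replace(
                syn, tasks=tuple(t for t in syn.tasks if t in config.tasks))
        study = generate_study(syn)
    else:
        study = load_study(config.input_dir)

    tasks = config.tasks
    ts_rows, value_rows, exclusion_rows, pair_rows = [], [], [], []
    n_pairs = 0
    for pid, task, ref, test in study.pairs():
        if tasks is not None and task not in tasks:
            continue
        n_pairs += 1
        log.info("processing %s / %s", pid, task)
        try:
            t_rows, v_rows, e_rows = _process_pair(ref, test, config.sparc)
        except ValueError as exc:
            log.warning("pair %s/%s excluded: %s", pid, task, exc)
            exclusion_rows.append({"participant": pid, "task": task,
                                   "system": "both", "parameter": "all",
                                   "reason": str(exc)})
            pair_rows.append({"participant": pid, "task": task, "retained": False})
            continue
        ts_rows += t_rows
        value_rows += v_rows
        exclusion_rows += e_rows
        pair_rows.append({"participant": pid, "task": task, "retained": True})
    if n_pairs == 0:
        raise ValueError("no recording pairs to process")

    timeseries = pd.DataFrame(
        ts_rows, columns=["participant", "task", "parameter", "r", "mae",
                          "n_frames", "units"])
    values = pd.DataFrame(
        value_rows, columns=["participant", "task", "system", "parameter",
                             "value", "units"])
    exclusions = pd.DataFrame(
        exclusion_rows, columns=["participant", "task", "system", "parameter",
                                 "reason"])
    pair_status = pd.DataFrame(pair_rows, columns=["participant", "task", "retained"])
    if pair_status.empty or not pair_status["retained"].any():
        raise ValueError(
            f"no recordings survived exclusions: {len(exclusion_rows)} exclusions")

    table1 = _aggregate_table1(timeseries)
    table2, ba_pairs = _aggregate_table2(values)

    report = StudyReport(table1, table2, values, timeseries, exclusions, pair_status)
    if outdir is not None:
        outdir = Path(outdir)
        report.write(outdir)
        config.to_yaml(outdir / "resolved_config.yaml")
        if config.plots:
            rows = [agr.bland_altman(a, b, parameter=p)
                    for p, (a, b) in ba_pairs.items()]
            agr.make_plots(rows, ba_pairs, outdir / "plots")
    return report


def _aggregate_table1(timeseries: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (task, parameter), grp in timeseries.groupby(["task", "parameter"], sort=True):
        r_mean, r_sd = agr.aggregate_r(grp["r"].to_numpy())
        mae = grp["mae"].to_numpy(dtype=float)
        rows.append({
            "task": task, "parameter": parameter, "n": len(grp),
            "r_mean": r_mean, "r_sd": r_sd,
            "mae_mean": float(mae.mean()),
            "mae_sd": float(np.std(mae, ddof=1)) if len(mae) > 1 else 0.0,
            "units": grp["units"].iloc[0],
        })
    return pd.DataFrame(rows, columns=["task", "parameter", "n", "r_mean", "r_sd",
                                       "mae_mean", "mae_sd", "units"])


def _aggregate_table2(values: pd.DataFrame):
    rows, ba_pairs = [], {}
    for (task, parameter), grp in values.groupby(["task", "parameter"], sort=True):
        wide = grp.pivot_table(index="participant", columns="system",
                               values="value", aggfunc="first")
        if "test" not in wide or "reference" not in wide:
            continue
        wide = wide.dropna(subset=["test", "reference"])
        if len(wide) < 2:
            continue
        a = wide["test"].to_numpy(dtype=float)
        b = wide["reference"].to_numpy(dtype=float)
        row = agr.bland_altman(a, b, parameter=parameter)
        ba_pairs[f"{task}:{parameter}"] = (a, b)
        rows.append({
            "task": task, "parameter": parameter, "n": row.n,
            "mean_test": row.mean_a, "mean_reference": row.mean_b,
            "mae": row.mae, "mae_sd": row.mae_sd, "bias": row.bias,
            "sd_diff": row.sd_diff, "loa_lower": row.loa_lower,
            "loa_upper": row.loa_upper, "p_bias": row.p_bias,
            "units": grp["units"].iloc[0],
        })
    table2 = pd.DataFrame(rows, columns=["task", "parameter", "n", "mean_test",
                                         "mean_reference", "mae", "mae_sd", "bias",
                                         "sd_diff", "loa_lower", "loa_upper",
                                         "p_bias", "units"])
    return table2, ba_pairs


# ---------------------------------------------------------------------------
# File-based studies
# ---------------------------------------------------------------------------

def save_study(study: StudySet, outdir) -> None:
    """Write a study to disk: wide-CSV trajectories per recording, one
    annotations CSV, and the ground-truth CSV."""
    outdir = Path(outdir)
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    ann_rows = []
    seen = set()
    for rec in study.recordings:
        write_trajectories(rec.trajectories,
                           rec_dir / f"{rec.participant_id}_{rec.task}_{rec.system}.csv")
        key = (rec.participant_id, rec.task)
        if key not in seen:
            seen.add(key)
            ann = rec.annotations
            ann_rows.append({"participant": rec.participant_id, "task": rec.task,
                             "start": ann.start, "end": ann.end,
                             "reps": ";".join(repr(r) for r in ann.reps)})
    pd.DataFrame(ann_rows).to_csv(outdir / "annotations.csv", index=False)
    study.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)


def load_study(indir) -> StudySet:
    """Load a study saved by :func:`save_study` (or laid out the same way)."""
    indir = Path(indir)
    ann_df = pd.read_csv(indir / "annotations.csv")
    annotations = {}
    for _, row in ann_df.iterrows():
        reps = ()
        if isinstance(row.get("reps"), str) and row["reps"].strip():
            reps = tuple(float(x) for x in row["reps"].split(";"))
        annotations[(row["participant"], row["task"])] = Annotations(
            float(row["start"]), float(row["end"]), reps)
    recordings = []
    for path in sorted((indir / "recordings").glob("*.csv")):
        parsed = _parse_recording_stem(path.stem)
        if parsed is None:
            warnings.warn(f"skipping unrecognized recording file {path.name}")
            continue
        pid, task, system = parsed
        traj = read_trajectories(path)
        recordings.append(TaskRecording(pid, task, system, traj,
                                        annotations[(pid, task)]))
    gt_path = indir / "ground_truth.csv"
    gt = pd.read_csv(gt_path) if gt_path.exists() else pd.DataFrame(
        columns=["participant", "task", "parameter", "value", "units"])
    config = SyntheticConfig()  # placeholder: file input carries no generator config
    return StudySet(tuple(recordings), gt, config)


def _parse_recording_stem(stem: str):
    """Parse '<participant>_<task>_<system>' stems (tasks may contain '_')."""
    from .trajectories import SYSTEMS, TASKS
    for system in SYSTEMS:
        if not stem.endswith(f"_{system}"):
            continue
        rest = stem[: -len(system) - 1]
        for task in TASKS:
            if rest.endswith(f"_{task}"):
                return rest[: -len(task) - 1], task, system
    return None
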