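"""File formats and run manifests.

Time series travel as CSV with a fixed documented header, models and
session logs as JSON / JSON-lines, and every output directory carries a
run manifest naming its seed, configuration and inputs so a run can be
reproduced exactly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import EmgRecording, EnvelopeRecording
from .task_engine import SessionLog, TrialResult

#: Column order of the raw-recording CSV format.
RECORDING_COLUMNS = ["time_s", "emg_fcr", "emg_fcu", "emg_ecrl", "emg_ecu",
                     "force_x_n", "force_y_n"]


def read_recording(path) -> EmgRecording:
    """Read a raw recording CSV, validating columns and the time grid."""
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if (dt <= 0).any():
        bad = int(np.argwhere(dt <= 0)[0][0]) + 2  # 1-based, after header
        raise ValueError(f"{path}: non-monotone time at row {bad}")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform time grid")
    if df.isna().any().any():
        rows = (np.nonzero(df.isna().any(axis=1).to_numpy())[0] + 2).tolist()
        raise ValueError(f"{path}: NaN values at rows {rows[:10]}")
    fs = 1.0 / dt[0]
    return EmgRecording(
        time=t,
        emg=df[RECORDING_COLUMNS[1:5]].to_numpy(dtype=float),
        force=df[RECORDING_COLUMNS[5:7]].to_numpy(dtype=float),
        fs=float(fs),
    )


def write_recording(rec: EmgRecording, path) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.emg, rec.force]),
        columns=RECORDING_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def write_envelope(rec: EnvelopeRecording, path) -> None:
    cols = ["time_s", "env_fcr", "env_fcu", "env_ecrl", "env_ecu",
            "force_x_n", "force_y_n"]
    df = pd.DataFrame(np.column_stack([rec.time, rec.envelope, rec.force]),
                      columns=cols)
    df.to_csv(path, index=False, float_format="%.12g")


def read_envelope(path) -> EnvelopeRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    fs = 1.0 / (t[1] - t[0]) if t.shape[0] > 1 else 1000.0
    return EnvelopeRecording(
        time=t,
        envelope=df[["env_fcr", "env_fcu", "env_ecrl", "env_ecu"]].to_numpy(float),
        force=df[["force_x_n", "force_y_n"]].to_numpy(float),
        fs=float(round(fs, 6)),
    )


def write_manifest(out_dir, *, seed=None, config=None, inputs=None,
                   stage: str = "") -> Path:
    """Write the RunManifest JSON that makes a run reproducible."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if is_dataclass(config):
        config = asdict(config)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": inputs or [],
    }
    path = out_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return path


def _trial_record(i: int, trial: TrialResult, traj_file: str | None) -> dict:
    return {
        "trial_id": i,
        "target": trial.target,
        "success": bool(trial.success),
        "time_to_success": trial.time_to_success,
        "task_latency": trial.task_latency,
        "null_latency": trial.null_latency,
        "null_at_task_reach": trial.null_at_task_reach,
        "trajectory_file": traj_file,
    }


def write_session_log(log: SessionLog, out_dir, *, seed=None,
                      write_trajectories: bool = True) -> Path:
    """Write a session: JSON-lines trial records plus trajectory CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj_dir = out_dir / "trajectories"
    records_path = out_dir / "trials.jsonl"
    with open(records_path, "w") as fh:
        for i, trial in enumerate(log.trials):
            traj_file = None
            if write_trajectories and trial.trajectory_null is not None:
                traj_dir.mkdir(exist_ok=True)
                traj_file = f"trajectories/trial_{i:03d}.csv"
                df = pd.DataFrame(
                    np.column_stack([trial.trajectory_null,
                                     trial.trajectory_force]),
                    columns=["null_x", "null_y", "force_x_n", "force_y_n"])
                df.to_csv(out_dir / traj_file, index=False,
                          float_format="%.9g")
            fh.write(json.dumps(_trial_record(i, trial, traj_file)) + "\n")
    meta = {"paradigm": log.paradigm, "smvf": log.smvf,
            "n_trials": len(log.trials), "seed": log.seed,
            "targets": log.targets}
    with open(out_dir / "session.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    write_manifest(out_dir, seed=seed if seed is not None else log.seed,
                   config=log.config, stage=f"session-{log.paradigm}")
    return records_path


def read_session_log(out_dir) -> SessionLog:
    """Re-load a written session (trajectories included when present)."""
    out_dir = Path(out_dir)
    with open(out_dir / "session.json") as fh:
        meta = json.load(fh)
    trials = []
    with open(out_dir / "trials.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            traj_null = traj_force = None
            if rec.get("trajectory_file"):
                path = out_dir / rec["trajectory_file"]
                if not path.exists():
                    raise FileNotFoundError(f"missing trajectory file {path}")
                df = pd.read_csv(path)
                traj_null = df[["null_x", "null_y"]].to_numpy(float)
                traj_force = df[["force_x_n", "force_y_n"]].to_numpy(float)
            trials.append(TrialResult(
                target=rec["target"], success=rec["success"],
                time_to_success=rec["time_to_success"],
                task_latency=rec.get("task_latency"),
                null_latency=rec.get("null_latency"),
                null_at_task_reach=rec.get("null_at_task_reach"),
                trajectory_null=traj_null, trajectory_force=traj_force))
    return SessionLog(paradigm=meta["paradigm"], trials=trials,
                      targets=meta.get("targets", []), smvf=meta.get("smvf"),
                      seed=meta.get("seed"))
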