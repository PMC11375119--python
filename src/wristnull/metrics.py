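"""Behavioural metrics computed from trial logs.

Covers the null-space session metrics (motion efficiency, time to success,
correction counting on the smoothed speed profile, force RMS, angular
reaching range) and the concurrent-session metrics (per-target success
rate, task/null latencies, and the phase decomposition of null-space
motion concurrency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocess import smooth_trajectory
from .task_engine import SessionLog, TrialResult

#: Fraction of the needed null-space movement below which a concurrency
#: trial is dropped as too small for robust measurement.
CONCURRENCY_EXCLUSION_FRAC = 0.15

#: Speed-peak criteria for correction counting: minimum prominence as a
#: fraction of the trial's peak speed, and minimum peak separation (s).
PEAK_HEIGHT_FRAC = 0.05
PEAK_MIN_SEPARATION_S = 0.1


def motion_efficiency(traj_null: np.ndarray, start: np.ndarray,
                      target: np.ndarray,
                      success_time: float | None = None,
                      fs: float = 1000.0) -> float:
    """Straight-line distance over path length, truncated at success.

    Equals 1 only for motion that is collinear and monotone toward the
    target; any detour or reversal lowers it.
    """
    traj = np.atleast_2d(np.asarray(traj_null, dtype=float))
    if success_time is not None:
        traj = traj[: int(round(success_time * fs))]
    path = np.linalg.norm(np.diff(traj, axis=0), axis=1).sum()
    direct = np.linalg.norm(np.asarray(target, dtype=float) -
                            np.asarray(start, dtype=float))
    if path <= 0:
        raise ValueError("zero path length; efficiency undefined")
    return float(direct / path)


def count_corrections(traj_null: np.ndarray, fs: float,
                      end_time: float | None = None,
                      cutoff: float = 3.0,
                      height_frac: float = PEAK_HEIGHT_FRAC,
                      min_separation_s: float = PEAK_MIN_SEPARATION_S) -> int:
    """Number of sub-movements: peaks of the smoothed speed profile.

    The 2-D trajectory is low-passed at 3 Hz, differentiated to a speed
    profile, and local maxima above ``height_frac`` of the trial's maximum
    speed and separated by at least ``min_separation_s`` are counted.  For
    successful trials pass the success time as ``end_time`` so counting
    stops when the target is reached.
    """
    traj = np.atleast_2d(np.asarray(traj_null, dtype=float))
    if end_time is not None:
        traj = traj[: int(round(end_time * fs))]
    if traj.shape[0] < int(0.5 * fs):
        raise ValueError("trajectory shorter than 0.5 s")
    smooth = smooth_trajectory(traj, fs, cutoff)
    speed = np.linalg.norm(np.diff(smooth, axis=0), axis=1) * fs
    vmax = speed.max()
    if vmax <= 1e-6:   # stationary cursor up to numerical noise
        return 0
    peaks, _ = find_peaks(speed, height=height_frac * vmax,
                          distance=max(1, int(round(min_separation_s * fs))))
    return int(peaks.size)


def force_rms(traj_force: np.ndarray) -> float:
    """Root mean square of the force magnitude across the trial, N."""
    f = np.atleast_2d(np.asarray(traj_force, dtype=float))
    if f.shape[0] == 0:
        raise ValueError("empty force trace")
    return float(np.sqrt(np.mean(np.sum(f ** 2, axis=1))))


@dataclass
class ReachingRange:
    """Angular span of null-space positions reached at the target radius."""

    stage: str                    # "exploration" | "reaching" | "union"
    constraint_mode: str          # "with" | "without" force constraint
    angles_deg: np.ndarray        # reached angles, degrees in [0, 360)
    range_deg: float              # circular span
    empty: bool = False


def _circular_span(angles_deg: np.ndarray) -> float:
    """Span of an angle set as 360 minus the largest circular gap."""
    if angles_deg.size == 0:
        return 0.0
    a = np.sort(np.mod(angles_deg, 360.0))
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return float(360.0 - gaps.max())


def reaching_range(traj_null: np.ndarray, traj_force: np.ndarray,
                   smvf: float, *, stage: str = "reaching",
                   constraint_mode: str = "with",
                   target_radius: float = 2.0,
                   radius_tolerance: float = 0.4,
                   force_threshold_frac: float = 0.04) -> ReachingRange:
    """Angles reached in the null-space at the target radius.

    A sample counts as a reached angle when its null magnitude lies within
    ``radius_tolerance`` of ``target_radius``; with ``constraint_mode =
    "with"`` the force-magnitude constraint of the task must also hold
    (the stricter, task-equivalent reading — its angle set is a subset of
    the unconstrained one).
    """
    traj_null = np.atleast_2d(np.asarray(traj_null, dtype=float))
    traj_force = np.atleast_2d(np.asarray(traj_force, dtype=float))
    mag = np.linalg.norm(traj_null, axis=1)
    sel = np.abs(mag - target_radius) <= radius_tolerance
    if constraint_mode == "with":
        sel &= np.linalg.norm(traj_force, axis=1) < force_threshold_frac * smvf
    elif constraint_mode != "without":
        raise ValueError("constraint_mode must be 'with' or 'without'")
    angles = np.degrees(np.arctan2(traj_null[sel, 1], traj_null[sel, 0])) % 360.0
    return ReachingRange(stage=stage, constraint_mode=constraint_mode,
                         angles_deg=angles, range_deg=_circular_span(angles),
                         empty=angles.size == 0)


def concurrency_phases(trial: TrialResult, baseline: float,
                       target_size: float,
                       exclusion_frac: float = CONCURRENCY_EXCLUSION_FRAC
                       ) -> Optional[tuple[float, float]]:
    """Split the required null-space movement into Phase 1 / Phase 2 shares.

    The needed movement is D = target_size - baseline, with the baseline
    taken from calibration holds at the matching task-space target (the
    involuntary null activity of plain force production).  Phase 1 is the
    share completed by the time the task-space target is reached, Phase 2
    the remainder; the two always sum to 1 and Phase 2 is negative when
    Phase 1 overshot the target size.  Trials with D below 15% of the
    target size are excluded (returns None).
    """
    if not trial.success or trial.null_at_task_reach is None:
        raise ValueError("concurrency needs a successful trial with a "
                         "recorded task-space reach")
    D = target_size - baseline
    if D < exclusion_frac * target_size:
        return None
    phase1 = (trial.null_at_task_reach - baseline) / D
    return float(phase1), float(1.0 - phase1)


def success_rate(session: SessionLog, by: str = "target") -> pd.DataFrame:
    """Fraction of successful trials per target group.

    ``by`` is "target" (full target identity), "position" or "size" (the
    latter two only for concurrent sessions).
    """
    rows = []
    for t in session.trials:
        tgt = t.target
        if by == "target":
            key = tuple(tgt.get("location", tgt.get("position", ()))) + \
                ((tgt["size"],) if "size" in tgt else ())
        elif by == "position":
            key = tuple(tgt["position"])
        elif by == "size":
            key = tgt["size"]
        else:
            raise ValueError(f"unknown grouping {by!r}")
        rows.append({"group": key, "success": t.success})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("session has no trials")
    out = df.groupby("group", sort=False)["success"].agg(["mean", "count"])
    return out.rename(columns={"mean": "success_rate", "count": "n_trials"})


def time_to_success_summary(session: SessionLog) -> pd.DataFrame:
    """Median and IQR of per-trial latencies grouped per target.

    For concurrent sessions the task- and null-space latencies are
    summarised alongside the joint time to success.
    """
    rows = []
    for t in session.trials:
        if not t.success:
            continue
        tgt = t.target
        key = tuple(tgt.get("location", tgt.get("position", ()))) + \
            ((tgt["size"],) if "size" in tgt else ())
        rows.append({"group": key, "time_to_success": t.time_to_success,
                     "task_latency": t.task_latency,
                     "null_latency": t.null_latency})
    if not rows:
        raise ValueError("no successful trials to summarise")
    df = pd.DataFrame(rows)

    def _iqr(x):
        x = x.dropna()
        if x.empty:
            return np.nan
        return float(np.percentile(x, 75) - np.percentile(x, 25))

    def _median(x):
        x = x.dropna()
        return float(np.median(x)) if not x.empty else np.nan

    agg = df.groupby("group", sort=False).agg(
        median_time=("time_to_success", _median),
        iqr_time=("time_to_success", _iqr),
        median_task_latency=("task_latency", _median),
        median_null_latency=("null_latency", _median),
        n_success=("time_to_success", "count"),
    )
    return agg


def session_metrics(session: SessionLog, fs: float = 1000.0) -> pd.DataFrame:
    """Tidy per-trial metrics table for a simulated session."""
    rows = []
    for i, t in enumerate(session.trials):
        row = {"trial_id": i, "success": t.success,
               "time_to_success": t.time_to_success}
        if t.trajectory_force is not None:
            row["force_rms"] = force_rms(t.trajectory_force)
        if t.success and t.trajectory_null is not None:
            start = t.trajectory_null[0]
            tgt = t.target.get("location")
            if tgt is not None:
                row["motion_efficiency"] = motion_efficiency(
                    t.trajectory_null, start, np.asarray(tgt),
                    t.time_to_success, fs)
            row["n_corrections"] = count_corrections(
                t.trajectory_null, fs, t.time_to_success)
        elif t.trajectory_null is not None and \
                t.trajectory_null.shape[0] >= int(0.5 * fs):
            row["n_corrections"] = count_corrections(t.trajectory_null, fs)
        row["task_latency"] = t.task_latency
        row["null_latency"] = t.null_latency
        rows.append(row)
    return pd.DataFrame(rows)
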