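"""Deterministic simulation of the two reaching paradigms.

Null-space target reaching (NSTR): the cursor is driven by (the negative
of) the rotated null-space coordinate n; a trial succeeds when the cursor
stays within the target tolerance for a full hold period while the exerted
force magnitude remains below a threshold fraction of sMVF.  Targets start
on the natural co-contraction direction at [2, 0] and rotate anticlockwise
in 5-degree steps once the participant reaches at least 80% of the last
ten trials at the current target.

Concurrent target reaching (CTR): cursor position is driven by force
(scaled by sMVF), cursor radius by the null-space magnitude; a trial
succeeds only when position and size are matched simultaneously through
the hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from .calibration import TARGET_FORCE_FRAC
from .nullspace import NullspaceModel


@dataclass
class NstrConfig:
    """Null-space target reaching session parameters."""

    n_trials: int = 80
    trial_duration: float = 7.0      # s
    hold_duration: float = 1.0       # s
    null_tolerance: float = 0.4      # rotated null units, ||e_n|| <= 0.4
    force_threshold_frac: float = 0.04   # of sMVF
    initial_target: tuple[float, float] = (2.0, 0.0)
    rotation_step: float = 5.0       # degrees, anticlockwise
    window: int = 10                 # moving window of trials
    success_frac: float = 0.8
    exploration_duration: float = 120.0  # s
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.success_frac <= 1):
            raise ValueError("success_frac must be in (0, 1]")
        for name in ("n_trials", "trial_duration", "hold_duration",
                     "null_tolerance", "force_threshold_frac",
                     "rotation_step", "window", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CtrConfig:
    """Concurrent target reaching session parameters.

    Positions are expressed as fractions of sMVF (the display scaling);
    the 8 ring targets sit at radius 0.2 and T9 is the origin.  Sizes are
    null-space magnitudes.  Position/size tolerances are not printed in the
    protocol and default to the thresholds reused from the null-space task.
    """

    n_trials: int = 90
    trial_duration: float = 7.0
    hold_duration: float = 1.0
    sizes: tuple[float, float] = (3.0, 6.0)
    position_tolerance: float = 0.04   # fraction of sMVF
    size_tolerance: float = 0.4        # null units
    fs: float = 1000.0

    @property
    def positions(self) -> np.ndarray:
        """(9, 2) task-space targets as sMVF fractions: 8-point ring then
        the origin (T9)."""
        ang = np.deg2rad(45.0 * np.arange(8))
        ring = TARGET_FORCE_FRAC * np.column_stack([np.cos(ang), np.sin(ang)])
        return np.vstack([ring, np.zeros((1, 2))])


@dataclass
class TrialResult:
    """Outcome of a single evaluated trial."""

    target: dict
    success: bool
    time_to_success: Optional[float]      # s, end of first valid hold
    task_latency: Optional[float] = None  # CTR: position reached (s)
    null_latency: Optional[float] = None  # CTR: size reached (s)
    null_at_task_reach: Optional[float] = None  # CTR: ||n|| at task reach
    violation_out_of_target: Optional[np.ndarray] = None
    violation_force: Optional[np.ndarray] = None
    trajectory_null: Optional[np.ndarray] = None
    trajectory_force: Optional[np.ndarray] = None


def _first_hold_end(ok: np.ndarray, n_hold: int) -> Optional[int]:
    """Index one past the end of the first run of >= n_hold True samples."""
    if ok.shape[0] < n_hold:
        return None
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= n_hold:
            return i + 1
    return None


def evaluate_nstr_trial(traj_null: np.ndarray, traj_force: np.ndarray,
                        target: np.ndarray, config: NstrConfig,
                        smvf: float) -> TrialResult:
    """Score one null-space reach.

    Success requires a contiguous window of ``hold_duration`` in which the
    rotated null coordinate stays within ``null_tolerance`` of the target
    while the force magnitude stays below the threshold.  Violations
    outside the hold window do not abort the trial.  The on-screen cursor
    is the negative of n; evaluation happens in n-space and the display
    sign is metadata only.
    """
    if smvf is None or smvf <= 0:
        raise ValueError("a positive sMVF is required")
    traj_null = np.atleast_2d(np.asarray(traj_null, dtype=float))
    traj_force = np.atleast_2d(np.asarray(traj_force, dtype=float))
    if traj_null.shape[0] != traj_force.shape[0]:
        raise ValueError("null and force trajectories are not time-aligned")
    target = np.asarray(target, dtype=float)
    in_target = np.linalg.norm(traj_null - target, axis=1) <= config.null_tolerance
    force_ok = np.linalg.norm(traj_force, axis=1) < config.force_threshold_frac * smvf
    n_hold = int(round(config.hold_duration * config.fs))
    end = _first_hold_end(in_target & force_ok, n_hold)
    return TrialResult(
        target={"location": target.tolist()},
        success=end is not None,
        time_to_success=None if end is None else end / config.fs,
        violation_out_of_target=~in_target,
        violation_force=~force_ok,
        trajectory_null=traj_null,
        trajectory_force=traj_force,
    )


def progression_update(history: Sequence[tuple[int, bool]],
                       current_target: np.ndarray,
                       config: NstrConfig) -> tuple[np.ndarray, bool]:
    """Adaptive target progression for the null-space task.

    ``history`` holds (target_id, success) per trial, most recent last.
    If the successes at the *current* target within the last ``window``
    trials reach ``success_frac * window``, the next target is the current
    one rotated anticlockwise by ``rotation_step`` about the origin
    (magnitude preserved); otherwise the target is unchanged.  Counting
    only current-target trials means eight consecutive successes suffice,
    so an ideal participant advances every eight trials.
    """
    if len(history) == 0:
        raise ValueError("history must be non-empty")
    current_id = history[-1][0]
    recent = history[-config.window:]
    n_success = sum(1 for tid, ok in recent if tid == current_id and ok)
    needed = config.success_frac * config.window
    if n_success >= needed:
        th = np.deg2rad(config.rotation_step)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return R @ np.asarray(current_target, dtype=float), True
    return np.asarray(current_target, dtype=float), False


@dataclass
class SessionLog:
    """All trials of one simulated session plus scheduling metadata."""

    paradigm: str                      # "nstr" | "ctr"
    trials: list[TrialResult] = field(default_factory=list)
    targets: list[dict] = field(default_factory=list)
    smvf: Optional[float] = None
    config: Optional[dict] = None
    seed: Optional[int] = None
    exploration_null: Optional[np.ndarray] = None
    exploration_force: Optional[np.ndarray] = None

    @property
    def n_success(self) -> int:
        return sum(t.success for t in self.trials)

    def distinct_nstr_targets(self) -> int:
        seen = {tuple(np.round(t.target["location"], 9)) for t in self.trials}
        return len(seen)


def run_nstr_session(controller: Callable, model: NullspaceModel,
                     config: NstrConfig, seed: int = 0) -> SessionLog:
    """Run the 80-trial null-space session closed-loop.

    ``controller(target, model, config, rng)`` must return a non-negative
    activation trajectory alpha(t) of shape (trial_samples, 4); the engine
    projects it, scores the trial and applies the progression rule.
    """
    if model.smvf is None:
        raise ValueError("model must carry sMVF for the force threshold")
    rng = np.random.default_rng(seed)
    target = np.asarray(config.initial_target, dtype=float)
    target_id = 0
    history: list[tuple[int, bool]] = []
    log = SessionLog(paradigm="nstr", smvf=model.smvf,
                     config=asdict(config), seed=seed)
    for _ in range(config.n_trials):
        alpha = np.asarray(controller(target, model, config, rng), dtype=float)
        if (alpha < 0).any():
            raise ValueError("controller emitted negative activation")
        force, null = model.project(alpha)
        result = evaluate_nstr_trial(null, force, target, config, model.smvf)
        history.append((target_id, result.success))
        log.trials.append(result)
        log.targets.append({"id": target_id, "location": target.tolist()})
        target, advanced = progression_update(history, target, config)
        if advanced:
            target_id += 1
    return log


def generate_ctr_schedule(config: CtrConfig, seed: int = 0) -> list[tuple[int, float]]:
    """Randomised (position index, size) pairs for the concurrent session."""
    rng = np.random.default_rng(seed)
    pos_idx = rng.integers(0, len(config.positions), size=config.n_trials)
    size_idx = rng.integers(0, len(config.sizes), size=config.n_trials)
    return [(int(p), float(config.sizes[s])) for p, s in zip(pos_idx, size_idx)]


def evaluate_ctr_trial(traj_null: np.ndarray, traj_force: np.ndarray,
                       position_frac: np.ndarray, size: float,
                       config: CtrConfig, smvf: float,
                       require_hold: bool = True) -> TrialResult:
    """Score one concurrent reach.

    Position condition: ||f / sMVF - position|| <= position_tolerance.
    Size condition: | ||n|| - size | <= size_tolerance, where ||n|| is the
    offset-corrected null magnitude that drives the cursor radius.  Success
    needs both through a full hold window (or simultaneously at any sample
    when ``require_hold`` is False, the reach-only criterion).

    Per-space latencies are the earliest times from which each condition
    holds continuously through the end of the successful joint hold, so
    the task/null split of a successful reach is well defined.
    """
    if smvf is None or smvf <= 0:
        raise ValueError("a positive sMVF is required")
    traj_null = np.atleast_2d(np.asarray(traj_null, dtype=float))
    traj_force = np.atleast_2d(np.asarray(traj_force, dtype=float))
    position_frac = np.asarray(position_frac, dtype=float)
    pos_ok = np.linalg.norm(traj_force / smvf - position_frac, axis=1) \
        <= config.position_tolerance
    null_mag = np.linalg.norm(traj_null, axis=1)
    size_ok = np.abs(null_mag - size) <= config.size_tolerance
    joint = pos_ok & size_ok
    n_hold = int(round(config.hold_duration * config.fs)) if require_hold else 1
    end = _first_hold_end(joint, n_hold)
    target = {"position": position_frac.tolist(), "size": size}
    if end is None:
        return TrialResult(target=target, success=False, time_to_success=None,
                           violation_out_of_target=~joint,
                           trajectory_null=traj_null, trajectory_force=traj_force)
    # earliest start of the unbroken per-condition run ending at `end`
    def _run_start(ok: np.ndarray) -> int:
        i = end - 1
        while i > 0 and ok[i - 1]:
            i -= 1
        return i
    t_task = _run_start(pos_ok)
    t_null = _run_start(size_ok)
    return TrialResult(
        target=target, success=True, time_to_success=end / config.fs,
        task_latency=t_task / config.fs, null_latency=t_null / config.fs,
        null_at_task_reach=float(null_mag[t_task]),
        violation_out_of_target=~joint,
        trajectory_null=traj_null, trajectory_force=traj_force,
    )
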