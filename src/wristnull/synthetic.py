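"""Synthetic participants: muscle geometries, calibration sessions and
closed-loop reaching sessions with known ground truth.

The generator emulates the assumed structure of the real recordings:
non-negative 4-muscle activations mapped linearly to 2-D wrist force
through a pulling matrix whose columns positively span the force plane
(an antagonist pair per axis), a preferred natural co-contraction
direction inside the muscle-to-force null-space, additive (optionally
signal-dependent) envelope noise, and trial-structured reaching driven by
minimum-jerk activation ramps.  Force scaling is chosen so the scaling
maximum voluntary force (sMVF) comes out near 10 N, putting the 0.2 sMVF
task-space targets near 2 N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linprog, nnls
from scipy.signal import butter, sosfilt

from .calibration import (EmgForceResults, MvfResult, N_MVF_DIRECTIONS,
                          CalibrationPoint, compute_mvf, compute_smvf,
                          fit_pulling_matrix, make_calibration_targets,
                          mvf_direction_schedule, points_from_recordings)
from .nullspace import NullspaceModel, build_nullspace_model, nullspace_basis, scale_basis
from .preprocess import EmgRecording, EnvelopeRecording, WARMUP_S
from .task_engine import (CtrConfig, NstrConfig, SessionLog, TrialResult,
                          evaluate_ctr_trial, evaluate_nstr_trial,
                          generate_ctr_schedule, progression_update)

#: Default additive envelope noise (envelope units).
DEFAULT_NOISE_SIGMA = 0.05

#: Co-contraction calibration ring radius, scaled null units.
COCONTRACTION_RING = 3.0


@dataclass
class MuscleGeometry:
    """Ground-truth linear muscle model of one synthetic participant."""

    H_true: np.ndarray                  # (2, 4) N per envelope unit
    alpha_rest: np.ndarray              # (4,) >= 0 resting envelope
    cocontraction_pattern: np.ndarray   # (4,) >= 0, unit norm, in ker(H)
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    signal_dependent_noise: float = 0.0  # std fraction of activation
    seed: int = 0

    def __post_init__(self) -> None:
        self.H_true = np.asarray(self.H_true, dtype=float)
        self.alpha_rest = np.asarray(self.alpha_rest, dtype=float)
        self.cocontraction_pattern = np.asarray(self.cocontraction_pattern,
                                                dtype=float)
        if np.linalg.norm(self.H_true @ self.cocontraction_pattern) > 1e-8:
            raise ValueError("co-contraction pattern is not in the kernel")
        if (self.cocontraction_pattern < 0).any() or (self.alpha_rest < 0).any():
            raise ValueError("activation patterns must be non-negative")

    @property
    def N_true(self) -> np.ndarray:
        return nullspace_basis(self.H_true)

    @property
    def N_scaled_true(self) -> np.ndarray:
        return scale_basis(self.N_true, self.H_true)[1]


# column direction templates, N per envelope unit: FCR and FCU pull
# flexion-ward (-X) with radial (+Y) / ulnar (-Y) components, ECRL and ECU
# extension-ward (+X) likewise
_COLUMN_TEMPLATE = np.array([
    [-4.0, -3.6, 4.4, 4.0],
    [1.6, -2.0, 2.0, -2.4],
])


def _positively_spans(H: np.ndarray) -> bool:
    """Do the 4 columns positively span the plane (origin interior)?"""
    ang = np.sort(np.arctan2(H[1], H[0]))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    return bool(gaps.max() < np.pi - 1e-9)


def make_wrist_geometry(seed: int = 0,
                        noise_sigma: float = DEFAULT_NOISE_SIGMA,
                        jitter: float = 0.12) -> MuscleGeometry:
    """Anatomically plausible random wrist geometry, deterministic per seed.

    Column directions are jittered around flexor/extensor templates until
    the positive-spanning invariant holds, a strictly positive kernel
    direction (the natural co-contraction pattern) is extracted by linear
    programming, and a small positive resting activation is drawn.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        H = _COLUMN_TEMPLATE * (1.0 + jitter * rng.standard_normal((2, 4)))
        if not _positively_spans(H) or np.linalg.matrix_rank(H) < 2:
            continue
        pattern = _positive_kernel_direction(H)
        if pattern is None:
            continue
        alpha_rest = rng.uniform(0.02, 0.05, size=4)
        return MuscleGeometry(H_true=H, alpha_rest=alpha_rest,
                              cocontraction_pattern=pattern,
                              noise_sigma=noise_sigma, seed=seed)
    raise RuntimeError("could not draw a positively spanning geometry")


def _positive_kernel_direction(H: np.ndarray) -> Optional[np.ndarray]:
    """A strictly positive unit vector in ker(H), or None."""
    res = linprog(c=np.ones(4), A_eq=H, b_eq=np.zeros(2),
                  bounds=[(1.0, None)] * 4, method="highs")
    if res.status != 0:
        return None
    p = res.x
    p = p - _project_rows(H, p)  # polish: remove residual force component
    if (p <= 0).any():
        return None
    return p / np.linalg.norm(p)


def _project_rows(H: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Component of v in the row space of H."""
    Q, _ = np.linalg.qr(H.T)
    return Q @ (Q.T @ v)


def inverse_activation(H: np.ndarray, N_scaled: np.ndarray,
                       desired_force: np.ndarray, desired_null: np.ndarray,
                       tol: float = 1e-6, clamp: bool = False) -> np.ndarray:
    """Non-negative activation realising a (force, unrotated-null) pair.

    Solves the stacked system [H; N_tilde] alpha = [f; n_tilde] by
    non-negative least squares.  Raises when the request is outside the
    non-negativity cone, unless ``clamp=True``, in which case the nearest
    attainable activation (the NNLS minimiser) is returned.
    """
    A = np.vstack([np.asarray(H, float), np.asarray(N_scaled, float)])
    b = np.concatenate([np.asarray(desired_force, float),
                        np.asarray(desired_null, float)])
    alpha, residual = nnls(A, b)
    if residual > tol * max(1.0, np.linalg.norm(b)) and not clamp:
        raise ValueError(
            f"(force, null) request infeasible under alpha >= 0: "
            f"residual {residual:.3g} exceeds tolerance; the request lies "
            f"outside the reachable cone")
    return alpha


@dataclass
class CalibrationSession:
    """All labelled recordings of one synthetic calibration block."""

    mvf: list          # (direction_deg, EnvelopeRecording) pairs
    holds: list        # (target_force (2,), EnvelopeRecording) pairs
    rest: EnvelopeRecording
    cocontraction: list  # 6 EnvelopeRecordings
    geometry: Optional[MuscleGeometry] = None
    fs: float = 1000.0

    def calibrate(self) -> tuple[MvfResult, EmgForceResults, NullspaceModel]:
        """Run the full calibration chain on the recorded blocks."""
        uniq = []
        mvf_values = []
        for d in mvf_direction_schedule():
            traces = [rec for dd, rec in self.mvf if np.isclose(dd, d)]
            if not traces:
                raise ValueError(f"missing MVF direction {d}")
            uniq.append(d)
            mvf_values.append(max(compute_mvf(rec.force, rec.fs) for rec in traces))
        mvf_res = MvfResult(directions_deg=np.array(uniq),
                            mvf=np.array(mvf_values),
                            smvf=compute_smvf(mvf_values))
        points = points_from_recordings(self.holds)
        fit = fit_pulling_matrix(points, smvf=mvf_res.smvf)
        model = fit.nullspace(self.rest, self.cocontraction)
        return mvf_res, fit, model


def _envelope_noise(rng: np.random.Generator, clean: np.ndarray,
                    geometry: MuscleGeometry) -> np.ndarray:
    noise = geometry.noise_sigma * rng.standard_normal(clean.shape)
    if geometry.signal_dependent_noise > 0:
        noise += geometry.signal_dependent_noise * clean * \
            rng.standard_normal(clean.shape)
    return noise


def _make_recording(alpha_clean: np.ndarray, geometry: MuscleGeometry,
                    rng: np.random.Generator, fs: float) -> EnvelopeRecording:
    """Envelope recording whose noiseless mean obeys f = H alpha."""
    n = alpha_clean.shape[0]
    envelope = np.clip(alpha_clean + _envelope_noise(rng, alpha_clean, geometry),
                       0.0, None)
    force = alpha_clean @ geometry.H_true.T
    t = np.arange(n) / fs
    return EnvelopeRecording(time=t, envelope=envelope, force=force, fs=fs,
                             warmup_s=WARMUP_S)


def _min_jerk(n: int) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n)
    return 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5


def _ramp_hold(alpha_from: np.ndarray, alpha_to: np.ndarray, fs: float,
               ramp_s: float, total_s: float) -> np.ndarray:
    """(n, 4) activation: minimum-jerk ramp then hold."""
    n_total = int(round(total_s * fs))
    n_ramp = min(int(round(ramp_s * fs)), n_total)
    s = np.ones(n_total)
    s[:n_ramp] = _min_jerk(n_ramp)
    return alpha_from + s[:, None] * (alpha_to - alpha_from)


def simulate_calibration_session(geometry: MuscleGeometry,
                                 rounds: int = 6, mvf_rounds: int = 2,
                                 fs: float = 1000.0,
                                 seed: int = 0,
                                 smvf_nominal: float = 10.0) -> CalibrationSession:
    """Synthesise a full calibration block (initial-session defaults:
    2 rounds of MVF production and 6 rounds of the 17-target reaches,
    plus the rest trial and 6 co-contraction repetitions).

    Maximum exertions ramp to direction-dependent maxima with the weakest
    direction near ``smvf_nominal``; target holds ramp for 2 s and hold
    for 2 s so the averaged final-2-s window sits on the plateau.
    """
    rng = np.random.default_rng(seed)
    H = geometry.H_true
    N_scaled = geometry.N_scaled_true

    # --- MVF exertions: weakest direction ~ smvf_nominal
    mvf_traces = []
    strength = smvf_nominal * (1.0 + 0.25 * rng.random(N_MVF_DIRECTIONS))
    strength[rng.integers(N_MVF_DIRECTIONS)] = smvf_nominal
    for _ in range(mvf_rounds):
        for i, d in enumerate(mvf_direction_schedule()):
            th = np.deg2rad(d)
            f_max = strength[i] * np.array([np.cos(th), np.sin(th)])
            # maximum exertion constrains force only; whatever null-space
            # activity comes with it is incidental
            alpha_max, _ = nnls(H, f_max)
            alpha_max = alpha_max + geometry.alpha_rest
            alpha = _ramp_hold(geometry.alpha_rest, alpha_max, fs,
                               ramp_s=2.0, total_s=4.0)
            mvf_traces.append((d, _make_recording(alpha, geometry, rng, fs)))

    smvf = min(compute_mvf(rec.force, rec.fs)
               for _, rec in mvf_traces)

    # --- 17-target holds, `rounds` rounds
    targets = make_calibration_targets(smvf)
    holds = []
    for _ in range(rounds):
        for tgt in targets:
            # force is tracked accurately (visual feedback); the null-space
            # activity that comes with it is whatever minimal non-negative
            # activation plus a resting floor produces
            alpha_tgt, _ = nnls(H, tgt)
            alpha_tgt = alpha_tgt + geometry.alpha_rest * 0.2
            alpha = _ramp_hold(geometry.alpha_rest, alpha_tgt, fs,
                               ramp_s=1.5, total_s=4.0)
            holds.append((tgt.copy(), _make_recording(alpha, geometry, rng, fs)))

    # --- rest trial
    n_rest = int(round(3.0 * fs))
    rest = _make_recording(np.tile(geometry.alpha_rest, (n_rest, 1)),
                           geometry, rng, fs)

    # --- 6 co-contraction repetitions growing the cursor to the
    # ||n_tilde|| = 3 ring (pre-offset units: the rest offset is only
    # measured afterwards)
    n0_true = N_scaled @ geometry.alpha_rest
    v = N_scaled @ geometry.cocontraction_pattern
    b = float(n0_true @ v)
    gain = (-b + np.sqrt(b * b + (v @ v) *
                         (COCONTRACTION_RING ** 2 - n0_true @ n0_true))) / (v @ v)
    cocon = []
    for _ in range(6):
        alpha_cc = geometry.alpha_rest + gain * geometry.cocontraction_pattern
        alpha = _ramp_hold(geometry.alpha_rest, alpha_cc, fs,
                           ramp_s=1.5, total_s=4.0)
        cocon.append(_make_recording(alpha, geometry, rng, fs))

    return CalibrationSession(mvf=mvf_traces, holds=holds, rest=rest,
                              cocontraction=cocon, geometry=geometry, fs=fs)


@dataclass
class ControllerPolicy:
    """Stylised participant behaviour for closed-loop simulation.

    kind "ideal" tracks targets exactly; "noisy" adds low-pass filtered
    activation noise; "biased" rotates every intended null-space direction
    by ``bias_deg`` (the consistent directional bias some participants
    showed relative to their calibrated co-contraction).
    """

    kind: str = "ideal"
    reaction_time: float = 0.5    # s before movement onset
    movement_time: float = 1.5    # s of minimum-jerk ramp
    noise_gain: float = 0.0       # envelope units of filtered noise
    bias_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ideal", "noisy", "biased"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "noisy" and self.noise_gain == 0.0:
            self.noise_gain = 0.05
        if self.kind == "biased" and self.bias_deg == 0.0:
            self.bias_deg = 180.0


def _apply_bias(policy: ControllerPolicy, goal: np.ndarray) -> np.ndarray:
    if not policy.bias_deg:
        return goal
    th = np.deg2rad(policy.bias_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return R @ goal


def _alpha_trajectory(model: NullspaceModel, policy: ControllerPolicy,
                      alpha_goal: np.ndarray, duration: float, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Reaction pause, minimum-jerk activation ramp, then hold."""
    alpha_start = inverse_activation(model.H, model.N_scaled,
                                     np.zeros(2), model.n0, clamp=True)
    n_total = int(round(duration * fs))
    n_react = min(int(round(policy.reaction_time * fs)), n_total)
    alpha = np.empty((n_total, 4))
    alpha[:n_react] = alpha_start
    alpha[n_react:] = _ramp_hold(alpha_start, alpha_goal, fs,
                                 policy.movement_time,
                                 (n_total - n_react) / fs)
    if policy.noise_gain > 0:
        sos = butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
        noise = sosfilt(sos, rng.standard_normal(alpha.shape), axis=0)
        alpha = alpha + policy.noise_gain * noise / max(np.abs(noise).max(), 1e-12)
    return np.clip(alpha, 0.0, None)


def _policy_alpha(model: NullspaceModel, policy: ControllerPolicy,
                  desired_force: np.ndarray, desired_null_rot: np.ndarray,
                  duration: float, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Activation trajectory realising a reach toward a (force, null) goal."""
    goal = _apply_bias(policy, np.asarray(desired_null_rot, dtype=float))
    null_pre = model.R_c.T @ goal + model.n0
    alpha_goal = inverse_activation(model.H, model.N_scaled,
                                    desired_force, null_pre, clamp=True)
    return _alpha_trajectory(model, policy, alpha_goal, duration, fs, rng)


def _feasible_size_goal(model: NullspaceModel, desired_force: np.ndarray,
                        size: float, tol: float = 1e-6) -> np.ndarray:
    """A rotated null-space goal of magnitude ``size`` attainable together
    with the requested force.

    Only the cursor radius is displayed in the concurrent task, so any
    null direction of the right magnitude solves it; the search fans out
    from the natural co-contraction axis (angle 0) until the joint
    (force, null) request becomes feasible.  When the involuntary null
    activity of the force production makes every direction at that radius
    unattainable, the force is held exactly and the null magnitude is
    brought as close to the request as possible (the failure mode real
    small-size ulnar-ward trials showed), which may or may not land
    within tolerance.
    """
    for ang in np.concatenate([[0.0], np.repeat(np.arange(2.5, 181, 2.5), 2) *
                               np.tile([1, -1], 72)]):
        th = np.deg2rad(ang)
        goal = size * np.array([np.cos(th), np.sin(th)])
        null_pre = model.R_c.T @ goal + model.n0
        try:
            inverse_activation(model.H, model.N_scaled, desired_force,
                               null_pre, tol=tol)
        except ValueError:
            continue
        return goal
    # force-exact fallback: minimise the null magnitude deviation subject
    # to H alpha = f via a heavily force-weighted non-negative least squares
    w = 1e6
    A = np.vstack([w * model.H, model.N_scaled])
    b = np.concatenate([w * np.asarray(desired_force, float), model.n0])
    alpha, _ = nnls(A, b)
    _, n = model.project(alpha)
    return np.asarray(n, dtype=float)


def make_nstr_controller(policy: ControllerPolicy):
    """Adapter producing the callback `run_nstr_session` expects."""
    def controller(target, model, config, rng):
        return _policy_alpha(model, policy, np.zeros(2), target,
                             config.trial_duration, config.fs, rng)
    return controller


def simulate_exploration(model: NullspaceModel, config: NstrConfig,
                         radius: float = 2.0, margin_deg: float = 3.0,
                         waypoint_hz: float = 20.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Free-exploration sweep across the reachable cone at target radius.

    Returns (force trajectory, null trajectory) covering the angular
    sector attainable with zero force, swept back and forth for the
    exploration period.
    """
    cone = model.cone_extreme_rays()
    if cone.contains_full_plane:
        lo, hi = -np.pi, np.pi
    else:
        ang = np.arctan2(cone.rays[:, 1], cone.rays[:, 0])
        lo, hi = float(ang.min()), float(ang.max())
        pad = np.deg2rad(margin_deg)
        lo, hi = lo + pad, hi - pad
    n_way = int(config.exploration_duration * waypoint_hz)
    sweep = lo + (hi - lo) * 0.5 * (1 - np.cos(
        np.linspace(0, 4 * np.pi, n_way)))
    alphas = []
    for th in sweep:
        target = radius * np.array([np.cos(th), np.sin(th)])
        null_pre = model.R_c.T @ target + model.n0
        alphas.append(inverse_activation(model.H, model.N_scaled,
                                         np.zeros(2), null_pre, clamp=True))
    way = np.array(alphas)
    n_samp = int(config.exploration_duration * config.fs)
    t_way = np.linspace(0, 1, n_way)
    t_all = np.linspace(0, 1, n_samp)
    alpha = np.column_stack([np.interp(t_all, t_way, way[:, j])
                             for j in range(4)])
    return model.project(alpha)


def simulate_session(geometry: MuscleGeometry, policy: ControllerPolicy,
                     paradigm: str, config=None, seed: int = 0,
                     model: NullspaceModel | None = None,
                     with_exploration: bool = False) -> SessionLog:
    """Closed-loop simulation of a full NSTR or CTR session.

    When no fitted ``model`` is supplied, a noiseless calibration of the
    geometry is run first and its model used as the display mapping; the
    policy then acts through that same mapping, mirroring a participant
    seeing the calibrated visualisation.
    """
    from .task_engine import run_nstr_session  # local to avoid cycle at import
    if model is None:
        quiet = MuscleGeometry(H_true=geometry.H_true,
                               alpha_rest=geometry.alpha_rest,
                               cocontraction_pattern=geometry.cocontraction_pattern,
                               noise_sigma=0.0, seed=geometry.seed)
        _, _, model = simulate_calibration_session(
            quiet, rounds=2, mvf_rounds=1, seed=seed).calibrate()
    if paradigm.lower() == "nstr":
        config = config or NstrConfig()
        log = run_nstr_session(make_nstr_controller(policy), model,
                               config, seed=seed)
        if with_exploration:
            force_exp, null_exp = simulate_exploration(model, config)
            log.exploration_null = null_exp
            log.exploration_force = force_exp
        return log
    if paradigm.lower() == "ctr":
        config = config or CtrConfig()
        if model.smvf is None:
            raise ValueError("model must carry sMVF")
        rng = np.random.default_rng(seed)
        schedule = generate_ctr_schedule(config, seed)
        log = SessionLog(paradigm="ctr", smvf=model.smvf,
                         config=None, seed=seed)
        for pos_idx, size in schedule:
            pos_frac = config.positions[pos_idx]
            f_des = pos_frac * model.smvf
            null_goal = _feasible_size_goal(model, f_des, size)
            alpha = _policy_alpha(model, policy, f_des, null_goal,
                                  config.trial_duration, config.fs, rng)
            force, null = model.project(alpha)
            result = evaluate_ctr_trial(null, force, pos_frac, size,
                                        config, model.smvf)
            result.target["position_index"] = pos_idx
            log.trials.append(result)
            log.targets.append({"position_index": pos_idx, "size": size})
        return log
    raise ValueError(f"unknown paradigm {paradigm!r}")


def synthesize_raw_emg(envelope: EnvelopeRecording, seed: int = 0,
                       band: tuple[float, float] = (20.0, 450.0)) -> EmgRecording:
    """Raw-EMG synthesis: band-limited noise carrier amplitude-modulated by
    the target envelope (for exercising the filter chain end to end).

    The carrier is unit-variance Gaussian noise band-passed to the typical
    surface-EMG band; modulating it by e(t) * sqrt(pi/2) makes the
    rectified mean of the product approximately e(t), so the extracted
    envelope tracks the requested one up to filter roll-off.
    """
    rng = np.random.default_rng(seed)
    fs = envelope.fs
    hi = min(band[1], 0.45 * fs)
    sos = butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    carrier = sosfilt(sos, rng.standard_normal(envelope.envelope.shape), axis=0)
    carrier /= carrier.std(axis=0, keepdims=True)
    raw = envelope.envelope * np.sqrt(np.pi / 2.0) * carrier
    return EmgRecording(time=envelope.time, emg=raw,
                        force=envelope.force.copy(), fs=fs)
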