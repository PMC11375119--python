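# Methods

## Model

The pipeline treats isometric wrist control as a quasi-static linear map
from muscle activation to force. The EMG envelope vector
α = [α_FCR, α_FCU, α_ECRL, α_ECU]ᵀ ≥ 0 produces planar force

    f = H α,          H ∈ R^{2×4},

with X = flexion–extension (extension positive) and Y = radial–ulnar
deviation (radial positive). H is estimated by ordinary least squares
with **no intercept**: the model is strictly proportional, the rest
calibration target anchors the origin, and any resting-envelope bias is
carried instead by the null-space offset n₀. This keeps the force
equation and the null-space coordinate equation consistent with each
other. Per-axis R² uses the force variance about its mean
(1 − SSR/SST), so a zero-variance axis is flagged undefined rather than
reported as a spurious 1.

The null-space coordinate shown to a (simulated) participant is

    n = R_c (κ N α − n₀),

where the rows of N form an orthonormal basis of ker H (computed by
SVD), κ = max(‖h₁‖, ‖h₂‖) scales null units so that a null magnitude of
β demands muscle effort comparable to producing β newtons along the
stronger force axis, n₀ = κN·ᾱ_rest from a dedicated rest trial, and R_c
is the proper rotation taking the mean natural co-contraction coordinate
n_c onto the +X axis. n_c is the mean of κN·ᾱ over six co-contraction
holds, with n₀ subtracted after averaging (equivalent for means).

Since muscles only pull, the attainable null-space set is not the plane
but the cone {R_c(κNα − n₀) : α ≥ 0}. Membership is decided as a linear
feasibility program over α ≥ 0 with equality constraints on the null
coordinate and (optionally) on force; the strict inequality α > 0 of the
idealised statement is relaxed to its closure, which is the numerically
decidable version, with equality tolerance 1e−7 in scaled units. The
cone's extreme rays are the two column images of R_c κN adjacent to the
largest angular gap; if every gap is below 180° the four columns
positively span the plane and the cone is the whole plane.

### Conventions and numerical choices

- Channel order is fixed everywhere: FCR, FCU, ECRL, ECU.
- 0° is +X (extension); the MVF schedule starts at 180° (flexion-ward)
  and proceeds anticlockwise in 22.5° steps. Per-direction MVF is the
  maximum force *magnitude* over the final 2 s of the 4 s exertion (a
  projection variant is exposed for sensitivity analysis); sMVF is the
  minimum across the 16 directions.
- The SVD basis is sign-ambiguous. Rows are canonicalised (largest
  element positive), and at model-build time the first row is flipped if
  needed so the pre-rotation co-contraction coordinate has non-negative
  first component; R_c absorbs the rest. This makes serialised models
  reproducible bit-for-bit.
- Envelope filtering is causal single-pass (matching a real-time
  feedback loop); a zero-phase option exists for offline use. Filters
  start from zero state and the first 0.5 s is flagged as warm-up and
  excluded from calibration averages. Negative low-pass ringing is
  clipped to 0 so α ≥ 0 holds exactly — non-negativity is load-bearing
  for the cone computation.
- Trajectory smoothing (3 Hz, before correction counting) is initialised
  at the trace's first sample, so a stationary cursor produces no
  start-up transient.

## Task simulation

**Null-space target reaching (NSTR).** 80 trials of 7 s; success needs a
contiguous 1 s hold with ‖n − target‖ ≤ 0.4 and ‖f‖ < 0.04·sMVF.
Violations outside the hold window do not abort a trial — the success
definition attaches conditions to the hold only. The displayed cursor is
the *negative* of n; evaluation is in n-space and the display sign is
metadata. The first target sits at [2, 0] (the natural co-contraction
direction); when at least 80% of the last ten trials at the current
target succeeded, the target rotates 5° anticlockwise about the origin.
Only trials at the *current* target count toward the window, so eight
consecutive successes suffice and a perfectly consistent agent visits
exactly ten target locations in 80 trials — the unique reading of the
windowed rule consistent with that count.

**Concurrent target reaching (CTR).** 90 trials over 9 task-space
positions (origin + 8 points at 0.2·sMVF) × 2 null sizes {3, 6}, drawn
uniformly with the session seed. Success needs a 1 s hold with
‖f/sMVF − p‖ ≤ 0.04 and |‖n‖ − size| ≤ 0.4 simultaneously; the cursor
radius is the offset-corrected null magnitude (rotation-invariant, so
‖ñ − n₀‖ = ‖n‖). The protocol does not print the CTR tolerances; the
defaults reuse the NSTR force threshold (as a position tolerance in sMVF
fractions) and the NSTR null tolerance (as the size tolerance), both
config-overridable and recorded in logs. Per-space latencies of a
successful trial are the earliest times from which each condition holds
continuously through the end of the joint hold. A reach-only mode
(`require_hold=False`) scores a single jointly-satisfied sample.
Return-to-centre gating between trials is modelled as an inter-trial
reset, not simulated dwell.

## Metrics

- *Motion efficiency*: straight-line distance over path length,
  trajectory truncated at the success time. ≤ 1 by construction for
  trajectories ending on target.
- *Corrections*: peaks of the speed profile after 3 Hz smoothing. The
  generic peak finder is parameterised: peaks must exceed 5% of the
  trial's maximum speed with ≥ 100 ms separation (suppresses numerical
  micro-peaks; both exposed). Traces with maximum speed below 1e−6
  units/s count zero. For successful trials counting stops at the
  success time.
- *Force RMS*: √mean‖f‖² across the trial.
- *Reaching range*: angles of samples whose null magnitude is within 0.4
  of the target radius 2 (the target tolerance reused as the radial
  band, which the protocol leaves unstated), optionally restricted by
  the force constraint; the span is circular — 360° minus the largest
  angular gap of the sorted angle set, well-defined for wrap-around.
- *Concurrency phases*: with baseline b (mean null magnitude over the
  final 2 s of the calibration hold at the matching force target; the
  origin target's baseline is the offset-corrected rest, ≈ 0), required
  movement D = size − b. Phase 1 = (‖n‖ at task reach − b)/D, Phase 2 is
  the remainder; the two sum to 1 exactly and Phase 2 is negative on
  overshoot. Trials with D < 15% of the target size are excluded as too
  small for robust measurement. Sizes use the null magnitude ‖ñ‖ (the
  cursor radius), not the rotated first coordinate; the alternative is
  noted but not used.
- Summaries are descriptive (medians, IQRs); hypothesis testing is out
  of scope.

## Synthetic participants

The generator emulates the assumed structure of real sessions, with
ground truth available for every stage:

- **Geometry**: pulling-matrix columns jittered (12% multiplicative)
  around anatomically plausible templates — flexors pulling −X,
  extensors +X, each pair split radially/ulnarly on Y — resampled until
  the four columns positively span the force plane. A strictly positive
  kernel direction (found by linear programming) serves as the natural
  co-contraction pattern; resting activation is drawn in [0.02, 0.05]
  envelope units.
- **Scaling**: maximum exertions ramp to direction-dependent maxima with
  the weakest direction at 10 N, so sMVF ≈ 10 N and the 0.2·sMVF targets
  sit near 2 N.
- **Noise**: additive Gaussian on the envelope (default σ = 0.05
  envelope units, i.e. ≈ 5% of a typical working activation), with an
  optional signal-dependent term (std proportional to activation, off by
  default). Recorded force is the force of the clean activation —
  envelope noise is measurement noise, not motor noise. Envelopes are
  clipped at zero, which biases near-silent channels upward and leaves a
  percent-level systematic error in the recovered H; recovery error is
  therefore dominated by this clipping bias, not by sample size.
- **Calibration session**: 2 rounds × 16 MVF exertions, 6 rounds × 17
  target holds (1.5 s minimum-jerk ramp, ≥ 2 s plateau so the averaged
  final-2-s window is steady), one 3 s rest trial, and 6 co-contraction
  repetitions that grow the cursor to the ‖ñ‖ = 3 ring in pre-offset
  units (the offset is only measured afterwards, so the offset-corrected
  ‖n_c‖ comes out somewhat below 3).
- **Closed loop**: controller policies (ideal / noisy / biased) plan a
  goal activation by non-negative least squares on the stacked
  (force, null) system of the *fitted* model — the participant acts
  through the calibrated visualisation — and execute a 0.5 s reaction,
  1.5 s minimum-jerk activation ramp and hold. Activation blending is
  convex, so trajectories stay non-negative and force/null coordinates
  interpolate linearly. In the concurrent task the policy fans out from
  the co-contraction axis for a feasible null direction of the requested
  magnitude; when none exists it holds force exactly and brings the null
  radius as close as possible — reproducing the characteristic failure
  of small-size targets in force directions with large involuntary null
  activity. The biased policy rotates intended null directions by a
  fixed angle (default 180°), reproducing the consistent directional
  bias that prevents any first-target success.
- **Raw EMG** (for exercising the filter chain): band-limited (20–450 Hz)
  unit-variance Gaussian carrier amplitude-modulated by
  e(t)·√(π/2), so the rectified mean matches the requested envelope up
  to filter roll-off (~10–15%).

### What the generator does *not* emulate

Posture changes and pulling-vector drift within a session, nonlinear or
fatigue-dependent EMG–force relations, electrode cross-talk, trial-to-
trial co-contraction variability structure, and human learning dynamics.
Passing tests therefore certify the *pipeline* — calibration algebra,
cone computation, task logic and metrics — under the stated linear
model, not behavioural predictions about real participants.

## Problem sizes

The test suite simulates full sessions at the native 1000 Hz where the
numbers matter (calibration recovery across 20 participants, 80-trial
closed-loop sessions) and drops to 100–200 Hz grids for brute-force
window-scan oracles, where the evaluator's semantics are rate-independent.
Parameter recovery is assessed as the median relative Frobenius error of
H over 20 seeded participants at σ = 0.05.

## Known limitations

- The null-space is asserted 2-dimensional (4 muscles − 2 DoF); higher
  degrees of redundancy are future work.
- OLS with envelope noise is an errors-in-variables fit; together with
  the clipping bias this floors the recovery error near 4% at σ = 0.05
  regardless of the number of calibration points.
- Cone membership treats boundary points as members (closure of α > 0);
  boundary membership within 1e−7 of the edge is reported as inside.
- The moving-window progression rule resets implicitly via its
  current-target filter; alternative readings of the windowed criterion
  (e.g. counting all trials) would make an ideal agent progress slower
  and visit fewer targets.
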