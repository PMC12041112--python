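# Methods

This note documents the models, defaults and numerical choices behind
`cogavoid`, and what the simulated data can and cannot tell you about real
participants.

## The paradigm model

An experiment is a sequence of phases over a fixed virtual room
(8 m × 8 m × 3 m, pedestal at the centre, CS presented 1 m above the
pedestal). The US is a 1-s sound of 80 dB at the source with a linear decay
of 25 % of the source level per meter, hence exactly inaudible at and beyond
4 m. Phase defaults:

| phase | trials/condition | reinforcement | CS (s) | US onset (s) | start (m) | movement |
|---|---|---|---|---|---|---|
| practice | — (40-s free walk) | — | — | — | — | free |
| pavlovian_acquisition | 8 | 0.75 | 9 | 8 | 2 | seated |
| avoidance_learning | 8 | 0.75 | 9 | 8 | 1 | free |
| transfer | 2 | 0 | 21 | — | 2.5 | free + coins |
| instructed_extinction | 8 | 0 | 9 | (8, nominal) | 4 | approach prompt |
| extinction_recall | 2 | 0 | 9 | (8, nominal) | 1 | free |
| reinstatement | 8 or 3 | 0 | 9 | (8, nominal) | 1 | free, 1 unsignalled US first |

ITIs are drawn from Uniform(9, 15) s (mean 12 s). Trial order within a phase
is a uniform random permutation of the two conditions (an optional
maximum-run-length constraint is off by default); which CS+ trials carry the
US is a uniform random subset of exactly `rate × n` trials — non-integer
counts are rejected rather than rounded so schedules are exactly
reproducible. CS-identity counterbalancing is deterministic by participant
parity. The practice phase emits phase events but no trial records, so trial
counts match the published per-experiment structure encoded in the `exp1` …
`exp5` templates.

Unsignalled reinstatement US events are logged as `us_on` rows with
condition `none` and are not trial records.

## The agent

Agents are deliberately minimal: the goal is data whose *measured* structure
(trial-level kinematic statistics and their condition contrasts) is
controllable, not behavioural realism.

Learning is trial-level: one delta-rule update per trial,
`V_c ← V_c + α(λ − V_c)` with `λ = 1` only if a US was delivered *and*
perceived — the agent must be inside the 4-m audible radius at US onset,
unless the experiment's speaker-vibration cue (`us_visual_cue`, on in
templates `exp2`–`exp5`) signals US occurrence at any distance. Under
Bernoulli reinforcement the stationary mean of V equals the reinforcement
rate, which the tests verify. An unsignalled US restores each condition's
association toward its historical peak by a fraction
`reinstatement_strength` — a memory-reactivation account of reinstatement:
after extinction drives V near 0, the CS+ association (large peak) recovers
while CS− (peak ≈ 0) does not, producing the return of differential
avoidance.

Movement integrates at the tracker rate (default 90 Hz, within the 80–120 Hz
band of consumer HMDs; a fixed time step, no variable frame times). Per
step, in order of precedence:

1. seated phases: no drive (positional noise only);
2. instructed approach (if the agent is compliant this trial,
   Bernoulli(`approach_compliance`)): walk toward the CS, stopping at
   `stand_close_distance`;
3. avoidance: if the effective association `V_c + w·V_{CS+}` (generalisation
   weight `w` applies to CS− only) exceeds `avoidance_threshold`, walk away
   from the CS until `preferred_safe_distance`;
4. transfer trials: walk toward the current search-task coin;
5. otherwise: drift.

Steps never exceed `walk_speed·dt` plus Gaussian positional noise whose
1-second displacement SD is `position_noise_sd`; positions are clipped 0.3 m
inside the walls; yaw follows the movement direction (or the CS bearing when
idle) plus heading noise. Defaults: α = 0.25, θ = 0.4, safe distance 4 m,
walk 1 m/s, compliance 0.9, generalisation 0.1, positional noise 0.05 m/√s,
heading noise 5°. `null_agent_params()` sets α = 0 (no learning, no drive) —
the null model for calibration; `initial_cs_plus_association` creates
pre-conditioned agents whose avoidance vigour can be graded via `walk_speed`
without learning-timing variability inflating the SD of condition
differences.

Traces cover the CS period only (trial time 0 = CS onset); ITIs advance the
session clock and reset the agent to the phase's starting point — the return
walk is not instrumented, matching the per-trial logging layout.

For efficiency, a trial with no movement drive (the entire null-agent case)
is generated vectorised from cumulative noise increments; this is the same
process as the scalar stepping loop (a bounds check falls back to the scalar
path in the rare case wall clipping would bind), and a test verifies the
scalar loop against per-step policy iteration in the deterministic limit.

## Kinematics

The seven statistics are computed over `[t0, t1)` with `t1` the phase's
scheduled US onset (8 s) for all 9-s trials — reinforced or not — and the
full CS period for 21-s transfer trials (configurable, since a
US-onset-bounded window is undefined for unreinforced 21-s trials).
Distances are horizontal (x, z) projections by default: locomotor avoidance
is horizontal and the pedestal height is constant; a 3-D mode exists.
Speeds are raw consecutive-sample finite differences (an optional
moving-average smoother, default off, is provided for noisy hardware
traces). Head angle is the absolute angle (0–180°) between the yaw heading
and the bearing to the CS; it is reported missing when yaw is absent rather
than inferred from displacement. Reaction time is the first sample at which
the head is displaced ≥ 0.7 m from its position at the window's first
sample — displacement from the onset position, not distance to the CS, so
moves toward the CS count too; trials that never reach the threshold are
censored (NaN in tables) and censored trials drop out of RT aggregation
pairwise, with a warning when a participant loses a condition entirely.

One hand-derived fixture anchors the implementation: a walk from 1 m to 4 m
at 1 m/s (stationary after 3 s) sampled at 90 Hz over an 8-s window has mean
distance 2473.5/720 ≈ 3.43542 m, max 4, min 1, path 3, max speed 1 and
reaction time 0.7 s. All seven statistics are additionally checked against
an independently coded brute-force per-sample oracle on 1000 random traces
to 1e-9 relative tolerance, and are invariant under time shifts and joint
handedness conversion of trace and CS position.

## Statistics

The primary contrast is the per-participant CS+ − CS− difference of a
phase's condition means. Cohen's d is the paired d_z (mean difference over
SD of differences) — consistent with the one-sided paired-t framing; a d_av
variant (mean difference over the average condition SD) is available.
Hedges' g applies J = 1 − 3/(4·df − 1), df = n − 1. The 95 % CI on g inverts
the noncentral-t distribution of the paired t statistic (a bootstrap is easy
to substitute; the pivot is exact under normality). Far-tail CDF underflow
in scipy's noncentral t is resolved by tail side, which only affects
extreme simulated effects.

Mixed models use statsmodels' `MixedLM` (REML; L-BFGS with Powell and
Nelder–Mead fallbacks): `DV ~ CS*trial_num + (1|ppid)` within phase and
`DV ~ CS*phase + trial_num + (1|ppid)` across exactly two phases, with
trial number — the within-phase index across conditions — entered as a
linear numeric predictor and CS coded 1 for CS+. The CS × phase interaction
is the extinction / reinstatement criterion; its sign follows the order the
two phases are supplied. Wald z p-values are reported and labelled
descriptive (no multiplicity correction). If all optimizers fail the result
falls back to the repeated-measures paired contrast on condition means,
flagged `rm_fallback`. The contract is the model structure plus calibration
and recovery: on the null (no CS effect) the CS test rejects at ~5 %, and a
known CS effect of 1.0 (participant SD 0.5, residual SD 0.5, 24 × 32 trials)
is recovered within 2 SE.

Sensitivity analysis solves `power(d; n, α, tails) = target` for the
smallest detectable d of a paired t test via the exact noncentral-t power
function (brentq to 1e-6). For n = 23…32 at 80 % power, α = 0.05 one-sided
it yields 0.53–0.45, a little above the classic normal approximation
`(z_{1−α} + z_{power})/√n` and within 0.03 of published G*Power outputs for
the same settings (which round differently and may have used slightly
different n).

## Problem sizes and what the tests show

The calibration suite runs 200 null cohorts of n = 24 (avoidance phase
only), 100 recovery replicates, and one avoider cohort of n = 24 on the full
reinstatement design; the graded-avoidance monotonicity check uses 8 cohorts
of n = 8 at five geometrically spaced walking speeds and a 30-Hz tracker.
These sizes make the whole suite a desk-scale run while keeping Monte-Carlo
error well inside the asserted bands.

Passing tests show that the *pipeline* is correct and calibrated: schedules
have exactly the specified structure, the measured statistics equal their
definitions, null data produce null results at the nominal rate, and agents
built to avoid produce the direction-level published pattern (CS+ > CS− in
avoidance, reduced difference under instructed extinction, recovery after a
reinstatement US). They do not show that effect *magnitudes* match human
data: simulated agents lack inter-individual strategy differences, partial
and fluctuating avoidance, posture/gait dynamics, or realistic head-yaw
behaviour, so standardized effects are far larger than the g ≈ 0.2–0.9
observed in people, and reaction-time distributions are not realistic.
Comparisons against the human dataset require the authors' published
trial-level data and are out of scope here.

## Known limitations

- Two-pedestal configurations validate but are not exercised by the
  simulator; room-colour (context) designs are configurable but unanalysed.
- The UXF column vocabulary is this package's own frozen set; a best-effort
  alias shim maps common spellings on read.
- Agent parameters are not fitted to data; estimation hooks are out of
  scope.
- The repeated-measures fallback covers only the CS main effect, not
  trial-number terms.
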