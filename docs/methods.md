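# Methods

This note records the model implemented by `gapcross`, the assumptions and
defaults behind each stage, the numerical choices, and the limits of what the
synthetic-data runs demonstrate.

## Problem

A walker approaching a cuboidal hole that spans the walkway chooses between
two traversal strategies: **OVER** (one extended step across the hole) and
**IN** (step down into the base, one or more steps through it, and a step
back up). The pipeline quantifies the mechanical cost of each strategy from
marker kinematics and asks which candidate control variable best explains
the observed choices.

Conventions used everywhere: +x is the walking direction, +z vertical up,
units are metres, seconds, kilograms and joules; frame intervals are
half-open `[start, end)`; g = 9.81 m s⁻². Hole geometry is expressed
relative to leg length *l* (standing greater-trochanter height): depths
0.1–0.5 *l*, lengths 0.5–1.1 *l* on a 5 × 5 grid (25 geometries).

## Synthetic data generator

The generator is a kinematic template, not a dynamic simulation. Its purpose
is to produce marker data with the statistical and kinematic features the
downstream stages consume, together with exact construction ground truth for
testing.

- **Footfall plan.** Two standing feet at t = 0, a fixed number of approach
  steps at the target speed, the traversal footfalls (base placements for
  IN; one crossing step for OVER), and recovery steps. Step period defaults
  to 0.53 s snapped to the 120 Hz frame grid so ground-truth events land on
  frames.
- **Feet.** Stance feet are exactly stationary; swings are cubic smoothstep
  interpolants (zero endpoint velocity) with a sinusoidal clearance arc.
- **Pelvis.** Monotone piecewise-cubic (PCHIP) interpolation through
  mid-support positions for forward progression and through the lower of
  each step's flanking footfall heights for vertical level (so the descent
  happens on the step down and the rise on the step up), plus a per-step
  vertical bob whose amplitude grows with relative step length
  (`A = A0 (L/L0)^γ`, defaults A0 = 0.022 m, γ = 3). The bob growth makes
  long crossing steps mechanically expensive, giving the OVER cost surface
  its length dependence.
- **Upper body.** Trunk of fixed length above the pelvis; arms swing
  antiphase with a small amplitude.
- **Noise and dropout.** Isotropic Gaussian marker jitter (default
  σ = 2 mm); optional dropout writes NaN samples for one marker over an
  interval (never zeros).
- **Sessions.** Per participant: 25 preferred-condition trials (one per
  geometry; the strategy comes from a pluggable choice model) plus enforced
  trials following the protocol reduction rules — an enforced IN for every
  geometry chosen OVER, and for each hole length never crossed OVER a single
  enforced OVER at the greatest depth. The default deterministic
  threshold choice model (13 per-participant thresholds on the forward
  cost-model advantage) yields exactly 580 trials for a 13-participant
  cohort. The thresholds were calibrated once against the default forward
  cost model to reproduce that trial-count arithmetic; they were not tuned
  against any downstream test statistic.
- **Choice datasets.** `generate_choice_dataset` draws Bernoulli choices
  from the logistic law at given advantages, for parameter-recovery studies.

Determinism: all stochastic paths are driven by `numpy.random.default_rng`
seeded from the trial or session seed; identical seeds give bit-identical
outputs.

## Kinematics

- **Filtering.** "Fourth-order zero-phase Butterworth, 6 Hz corner" is
  realised as a 2nd-order filter run forward and backward (`scipy
  filtfilt`), with the dual-pass corner correction `(√2 − 1)^(−1/4)` so the
  effective magnitude response is −3 dB at the nominal corner (a unit 6 Hz
  sinusoid comes out at 1/√2).
- **Stance detection.** A stance phase is a maximal run in which both the
  fifth-metatarsal and malleolus markers move slower than 20% of the trial's
  mean forward speed for at least 100 ms, with edges refined to a 5% tight
  threshold. Thresholds are configurable; defaults were validated against
  generator ground truth (events within one frame on noise-free trials).
- **Steps.** A step spans `[stance_start(side), stance_start(contralateral))`.
  Step length is the horizontal distance between the flanking footfalls'
  malleolus positions, each taken at its own stance-phase midpoint (midpoints
  are robust to event-edge jitter). Quiet standing puts near-simultaneous
  stance starts on both sides; a stance contained in a longer opposite-side
  stance that starts within the minimum stance duration of it is treated as
  the standing tie and dropped, since the foot that swings first contributes
  no step boundary.
- **Traversal.** IN: all steps from the lead-leg step down into the base to
  the trail-leg step back up, inclusive (k base placements → k + 2 traversal
  steps); OVER: exactly the lead and trail crossing steps. The approach step
  is three steps before the first traversal step; trials without three prior
  steps are flagged.
- **Froude number.** Fr = v / √(g·l). This is the standard dimensionless
  speed; a published variant prints v(gl)⁻¹, which is not dimensionless, and
  is deliberately not implemented.

## Energetics

- **Body model.** 11 segments (head+trunk, and left/right upper arm,
  forearm+hand, thigh, shank, foot) defined by proximal/distal markers;
  segment CoM at the tabulated fraction along the chord. Default relative
  masses, CoM locations and gyration radii are Winter's standard
  anthropometric values; any table whose relative masses sum to 1 ± 0.005
  can be substituted (plain-text key-value file).
- **Work.** Positive-increment method: W = Σ max(0, ΔE) frame to frame, so
  work is additive over a partition of a window and invariant to the
  potential-energy datum. CoM work uses whole-body CoM kinetic + potential
  energy. Internal work uses five energy pools — trunk, each arm, each
  leg — in the CoM-relative frame: energies are summed within a pool before
  rectification (within-limb exchange allowed) and rectified separately
  across pools (between-limb exchange forbidden). W_tot = W_com + W_int by
  construction, so CoT_tot ≥ CoT_CoM always.
- **Rotational kinetic energy** (½·m·(kL)²·ω² per segment) is available via
  `include_rotational` but off by default; the source analysis does not
  state whether it was included.
- **Cost of transport.** CoT = W / (m·d), with task distance the sum of
  traversal step lengths and per-step windows tiling the task, so per-step
  work fractions sum to one.
- **Velocities** by central differences on filtered positions (one-sided at
  the ends).

## Forward cost model

Predicted metabolic CoT surfaces over the geometry grid:

- OVER: baseline + quadratic penalty in the relative step-length extension
  beyond the preferred step length; independent of depth; required steps
  beyond a feasible maximum are flagged infeasible.
- IN: baseline + (c_down + c_up)·depth_rel with c_up > c_down > 0;
  independent of length.

Defaults (baseline 2.5 J kg⁻¹ m⁻¹, quadratic coefficient 10, c_down 1,
c_up 4, preferred step 0.75 *l*, maximum step 1.5 *l*) are **calibration
placeholders** with the stated functional forms: the empirical coefficients
behind the published surfaces are not reproduced in the source text. All
tests depend only on the qualitative structure (baseline at zero
perturbation, monotonicity, surfaces intersecting within the grid), never on
the default values. The strategy boundary is located by a row-wise sign scan
of the cost difference, seeded by linear interpolation and refined with a
root finder on the continuous cost functions.

## Decision analysis

- **Advantage.** For each geometry and candidate variable, x is the absolute
  difference of the per-strategy means, signed positive when OVER is
  favoured: lower cost (task or worst-step CoT, total or CoM), higher
  traversal speed (speed_max), or smaller |approach − traversal| speed
  deviation (speed_conservation). Speeds are Froude-normalised. Candidate
  means pool preferred and enforced trials; choice counts come from
  preferred trials only. Geometries observed under a single strategy are
  flagged and excluded from fitting.
- **Logistic fit.** `ln(p/(1−p)) = b0 + b1·x`, maximum likelihood via
  statsmodels GLM (binomial family, IRLS, tolerance 1e-8), per-trial
  Bernoulli observations or equivalently count-weighted binomial. Wald
  standard errors, two-sided normal tests, 95% CI = estimate ± 1.96·SE.
  (Quasi-)perfect separation is reported as `converged=False` with a
  diagnostic, never silently.
- **Verdict.** A candidate is *consistent* with energy-optimal choice when
  (i) b1 > 0 with p < α (default 0.05, no multiple-testing correction) and
  (ii) the b0 95% CI contains zero (no bias at zero advantage). The point of
  subjective equality is −b0/b1.
- Trials are pooled across participants per geometry; per-participant random
  effects are not modelled (documented limitation).

## Pipeline and QC

`run_pipeline` sequences simulate → QC → kinematics → energetics →
advantages → fits → verdicts, writes every table as CSV plus a run log with
seeds and per-stage counts, and leaves an `INCOMPLETE` marker file if any
stage aborts. QC discards any trial with a gap in a required marker
(default configuration: 6 dropout trials in 580, leaving 574). Reruns with
identical config and seed are bit-identical.

## What the synthetic runs do and do not show

Passing tests demonstrate that the pipeline machinery is correct: filters
meet their closed-form response, work computations match dense-grid and
analytic oracles, event/step/CoM round trips recover generator ground truth
within a frame / millimetre, the logistic fitter matches independent
optimizers, the protocol arithmetic (580 → 574 trials, 25 geometries) is
exact, and logistic parameter recovery at the empirical design scale is
unbiased.

They do **not** reproduce the empirical coefficient values of the original
study: the generator's walkers choose via thresholds on the *forward
cost-model* advantage, while the fitted advantages are *measured* from the
synthetic kinematics, so the fitted intercepts absorb the offset between
the two scales (visible as non-zero b0 in full-pipeline runs). The forward
cost coefficients are placeholders; substitute measured coefficients for
quantitative use.

## Key defaults

| Parameter | Default | Notes |
|---|---|---|
| Frame rate | 120 Hz | generator and IO |
| Filter | 4th-order zero-phase Butterworth, 6 Hz | dual-pass corrected |
| Stance thresholds | 20% coarse / 5% refine of mean speed, ≥100 ms | configurable |
| Marker jitter | σ = 2 mm | generator |
| Step period | 0.53 s (frame-snapped) | generator |
| Approach speed | N(1.3, 0.1) m s⁻¹, clipped ≥ 0.6 | per trial |
| Participants | 13; mass N(72.3, 15.5) kg; leg N(0.88, 0.04) m | clipped to plausible ranges |
| Anthropometrics | Winter's table, hand folded into forearm | substitutable |
| Rotational KE | off | configurable |
| α | 0.05, two-sided | no multiplicity correction |
| g | 9.81 m s⁻² | fixed |
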