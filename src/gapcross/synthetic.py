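"""Synthetic motion-capture trials for hole-crossing walking tasks.

The generator emulates the statistical and kinematic structure the analysis
pipeline consumes: 14 anatomical markers sampled at 120 Hz while a walker
approaches a cuboidal hole in a raised trackway and traverses it either by
stepping across the gap (OVER) or by stepping down into the base and back up
(IN).  Feet are exactly stationary during designed stance phases, swing
trajectories are smooth interpolants with zero-velocity endpoints, the
pelvis follows a per-step vertical oscillation superposed on the
obstacle-induced support-height profile, and arm markers swing with small
amplitude.  Gaussian jitter (default sigma 2 mm) and optional marker dropout
emulate measurement noise and camera occlusion.

Every trial carries its construction ground truth (stance intervals,
footfall positions, designed step lengths, traversal step indices and the
designed pelvis height profile) in ``MarkerTrajectorySet.meta["truth"]`` so
downstream event detection, step segmentation and centre-of-mass work can be
verified by round trip.

The vertical-oscillation amplitude of a step grows with its length
(``A = A0 * (L / L0) ** gamma``): long crossing steps therefore cost more
mechanical work, and stepping down/up through the hole costs work roughly
proportional to hole depth, reproducing the qualitative cost structure the
analysis is designed to measure.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import expit

from .types import (
    MarkerTrajectorySet,
    Obstacle,
    Participant,
    TrialSpec,
    standard_grid,
)

__all__ = [
    "GeneratorParams",
    "TrialTruth",
    "generate_trial_markers",
    "generate_session",
    "generate_choice_dataset",
    "ThresholdChoiceModel",
    "LogisticChoiceModel",
    "DEFAULT_THRESHOLDS",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Kinematic template parameters (metres, seconds, radians)."""

    frame_rate: float = 120.0
    step_duration: float = 0.53        # time between consecutive footfalls
    swing_fraction: float = 0.8        # swing time as fraction of step duration
    stand_duration: float = 0.6        # initial quiet standing
    tail_duration: float = 0.5         # quiet standing after the last footfall
    n_steps_before: int = 5            # walking footfalls before the hole
    n_steps_after: int = 4             # walking footfalls after the crossing
    setback: float = 0.08              # last rim footfall to hole edge
    landing_margin: float = 0.12       # OVER landing beyond the far edge
    exit_margin: float = 0.10          # IN exit footfall beyond the far edge
    clearance: float = 0.06            # swing-foot arc height
    bob_amplitude: float = 0.022       # pelvis vertical oscillation, preferred steps
    bob_gamma: float = 3.0             # amplitude growth exponent with step length
    jitter_sigma: float = 0.002        # marker noise s.d. per coordinate
    max_step_rel: float = 1.5          # longest crossable step, fraction of leg length
    stagger: float = 0.15              # standing foot fore-aft offset
    ankle_height: float = 0.07
    mt5_height: float = 0.03
    mt5_forward: float = 0.15
    hip_halfwidth: float = 0.10
    shoulder_halfwidth: float = 0.18
    trunk_length_rel: float = 0.56     # mid-hip to mid-shoulder, fraction of leg length
    upper_arm_rel: float = 0.37
    forearm_rel: float = 0.30
    arm_amplitude: float = 0.25


@dataclass
class TrialTruth:
    """Construction ground truth for one synthetic trial."""

    stances: dict[str, list[tuple[int, int]]]
    footfalls: list[tuple[str, int, float, float]]  # (side, frame, x, z)
    step_lengths: np.ndarray          # designed length of step j (footfall j+1 -> j+2)
    traversal_steps: tuple[int, int]  # inclusive (first, last) detected-step indices
    approach_index: int
    pelvis_z: np.ndarray              # designed greater-trochanter height per frame
    com_z: np.ndarray                 # whole-body CoM height of the noiseless construction
    mean_speed: float
    obstacle_span: tuple[float, float]

    @property
    def n_traversal_steps(self) -> int:
        a, b = self.traversal_steps
        return b - a + 1


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def _plan_footfalls(spec: TrialSpec, p: GeneratorParams):
    """Return (positions [(x, z)], landing frame times) for all footfalls.

    Footfall 0 and 1 are the standing feet at t = 0; walking footfalls land
    every step_duration thereafter.  Even indices are the right foot.
    """
    obstacle = spec.obstacle
    fps = p.frame_rate
    # snap the step and swing durations to the frame grid so that ground
    # truth events fall exactly on frames
    t_step = round(p.step_duration * fps) / fps
    step_len = spec.approach_speed_target * t_step

    approach = [j * step_len for j in range(p.n_steps_before)]
    x_rim = approach[-1]
    x0 = x_rim + p.setback  # hole leading edge
    positions: list[tuple[float, float]] = [
        (-step_len - p.stagger, 0.0),
        (-step_len, 0.0),
    ] + [(x, 0.0) for x in approach]

    if spec.strategy == "IN":
        k = spec.steps_in_base
        for j in range(1, k + 1):
            positions.append(
                (x0 + obstacle.length_abs * j / (k + 1), -obstacle.depth_abs)
            )
        positions.append((x0 + obstacle.length_abs + p.exit_margin, 0.0))
    else:
        cross = p.setback + obstacle.length_abs + p.landing_margin
        if cross > p.max_step_rel * spec.participant.leg_length:
            raise ValueError(
                f"required crossing step {cross:.2f} m exceeds the maximum "
                f"crossable step ({p.max_step_rel:.2f} x leg length); "
                "OVER strategy infeasible for this obstacle"
            )
        positions.append((x0 + obstacle.length_abs + p.landing_margin, 0.0))
    for _ in range(p.n_steps_after):
        positions.append((positions[-1][0] + step_len, 0.0))

    n = len(positions)
    times = [0.0, 0.0] + [p.stand_duration + (i - 1) * t_step for i in range(2, n)]
    return positions, times, x0, t_step, step_len


def generate_trial_markers(
    spec: TrialSpec, params: GeneratorParams | None = None
) -> MarkerTrajectorySet:
    """Generate the 14-marker trajectory set for one trial.

    Deterministic for a fixed (spec, params): the jitter stream is seeded by
    ``spec.seed``.
    """
    p = params or GeneratorParams()
    part = spec.participant
    leg = part.leg_length
    fps = p.frame_rate
    positions, times, x0, t_step, step_len = _plan_footfalls(spec, p)
    n_ff = len(positions)
    t_swing = round(p.swing_fraction * t_step * fps) / fps

    t_end = times[-1] + p.tail_duration
    n_frames = int(round(t_end * fps)) + 1
    t = np.arange(n_frames) / fps

    sides = ["right" if i % 2 == 0 else "left" for i in range(n_ff)]
    land_frames = [int(round(ti * fps)) for ti in times]

    # ---- foot paths and designed stance intervals -------------------------
    foot_xy: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    stances: dict[str, list[tuple[int, int]]] = {"left": [], "right": []}
    for side in ("left", "right"):
        own = [i for i in range(n_ff) if sides[i] == side]
        x = np.empty(n_frames)
        z = np.empty(n_frames)
        for a, b in zip(own, own[1:]):
            i_land, i_next = land_frames[a], land_frames[b]
            i_sw = i_next - int(round(t_swing * fps))
            x[i_land:i_sw] = positions[a][0]
            z[i_land:i_sw] = positions[a][1]
            stances[side].append((i_land, i_sw))
            u = (np.arange(i_sw, i_next) - i_sw) / (i_next - i_sw)
            s = _smoothstep(u)
            x[i_sw:i_next] = positions[a][0] + (positions[b][0] - positions[a][0]) * s
            z[i_sw:i_next] = (
                positions[a][1]
                + (positions[b][1] - positions[a][1]) * s
                + p.clearance * np.sin(np.pi * u)
            )
        last = own[-1]
        x[land_frames[last]:] = positions[last][0]
        z[land_frames[last]:] = positions[last][1]
        stances[side].append((land_frames[last], n_frames))
        foot_xy[side] = (x, z)

    # ---- pelvis: forward progression, support level, vertical bob --------
    knot_t = [0.0] + list(times[2:]) + [t_end]
    mid_x = lambda i: 0.5 * (positions[i - 1][0] + positions[i][0])
    low_z = lambda i: min(positions[i - 1][1], positions[i][1])
    knot_x = [0.5 * (positions[0][0] + positions[1][0])]
    knot_x += [mid_x(i) for i in range(2, n_ff)]
    knot_x += [mid_x(n_ff - 1)]
    knot_z = [0.0] + [low_z(i) for i in range(2, n_ff)] + [low_z(n_ff - 1)]
    pelvis_x = PchipInterpolator(knot_t, knot_x)(t)
    level = PchipInterpolator(knot_t, knot_z)(t)

    bob = np.zeros(n_frames)
    for i in range(2, n_ff - 1):
        f0, f1 = land_frames[i], land_frames[i + 1]
        length_i = abs(positions[i + 1][0] - positions[i][0])
        amp = min(p.bob_amplitude * (length_i / step_len) ** p.bob_gamma, 0.18)
        u = (np.arange(f0, f1) - f0) / (f1 - f0)
        bob[f0:f1] = amp * (1.0 - np.cos(2.0 * np.pi * u)) / 2.0
    pelvis_z = leg + level + bob

    # ---- upper body -------------------------------------------------------
    trunk_len = p.trunk_length_rel * leg
    sho_z = pelvis_z + trunk_len
    sho_x = pelvis_x + 0.01  # slight forward lean

    stride = 2.0 * t_step
    phase = 2.0 * np.pi * (t - p.stand_duration) / stride
    ramp = np.clip((t - p.stand_duration) / 0.3, 0.0, 1.0) * np.clip(
        (times[-1] - t) / 0.3, 0.0, 1.0
    )
    ua, fa = p.upper_arm_rel * leg, p.forearm_rel * leg

    markers: dict[str, np.ndarray] = {}
    for side, sign in (("L", +1.0), ("R", -1.0)):
        side_name = "left" if side == "L" else "right"
        fx, fz = foot_xy[side_name]
        y_foot = sign * p.hip_halfwidth
        markers[f"{side}_ANK"] = np.column_stack(
            [fx, np.full(n_frames, y_foot), fz + p.ankle_height]
        )
        markers[f"{side}_MT5"] = np.column_stack(
            [fx + p.mt5_forward, np.full(n_frames, y_foot), fz + p.mt5_height]
        )
        hip = np.column_stack(
            [pelvis_x, np.full(n_frames, sign * p.hip_halfwidth), pelvis_z]
        )
        markers[f"{side}_HIP"] = hip
        ank = markers[f"{side}_ANK"]
        knee = hip + 0.47 * (ank - hip)
        knee[:, 0] += 0.03
        markers[f"{side}_KNEE"] = knee
        sho = np.column_stack(
            [sho_x, np.full(n_frames, sign * p.shoulder_halfwidth), sho_z]
        )
        markers[f"{side}_SHO"] = sho
        theta = sign * p.arm_amplitude * np.sin(phase) * ramp
        elb = sho + np.column_stack(
            [ua * np.sin(theta), np.full(n_frames, sign * 0.03), -ua * np.cos(theta)]
        )
        markers[f"{side}_ELB"] = elb
        th2 = 1.2 * theta
        markers[f"{side}_WRI"] = elb + np.column_stack(
            [fa * np.sin(th2), np.zeros(n_frames), -fa * np.cos(th2)]
        )

    # ---- ground-truth CoM of the noiseless construction --------------------
    from .energetics import com_trajectory

    clean = MarkerTrajectorySet(fps, {k: v.copy() for k, v in markers.items()}, part)
    com_z = com_trajectory(clean).com[:, 2]

    # ---- jitter and dropout ----------------------------------------------
    if p.jitter_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for label in markers:
            markers[label] = markers[label] + rng.normal(
                0.0, p.jitter_sigma, size=markers[label].shape
            )
    if spec.dropout is not None:
        label, a, b = spec.dropout
        if label not in markers:
            raise KeyError(f"dropout marker {label!r} unknown")
        if not (0 <= a < b <= n_frames):
            raise ValueError("dropout interval outside trial duration")
        markers[label][a:b] = np.nan

    # ---- ground truth ------------------------------------------------------
    footfalls = [
        (sides[i], land_frames[i], positions[i][0], positions[i][1])
        for i in range(n_ff)
    ]
    # detected steps are bounded by stance starts of footfalls 1..n_ff-1
    step_lengths = np.array(
        [abs(positions[j + 2][0] - positions[j + 1][0]) for j in range(n_ff - 2)]
    )
    nb = p.n_steps_before
    if spec.strategy == "IN":
        trav = (nb, nb + 1 + spec.steps_in_base)
    else:
        trav = (nb, nb + 1)
    truth = TrialTruth(
        stances=stances,
        footfalls=footfalls,
        step_lengths=step_lengths,
        traversal_steps=trav,
        approach_index=trav[0] - 3,
        pelvis_z=pelvis_z,
        com_z=com_z,
        mean_speed=spec.approach_speed_target,
        obstacle_span=(x0, x0 + spec.obstacle.length_abs),
    )
    meta = {
        "trial_id": spec.trial_id,
        "strategy": spec.strategy,
        "condition": spec.condition,
        "obstacle": spec.obstacle,
        "obstacle_x0": x0,
        "seed": spec.seed,
        "truth": truth,
    }
    return MarkerTrajectorySet(fps, markers, part, meta)


# --------------------------------------------------------------------------
# choice models and session plans
# --------------------------------------------------------------------------

#: Per-participant thresholds (on the model-predicted OVER cost advantage,
#: J kg^-1 m^-1) of the default deterministic choice model.  The mix of
#: mostly sign-followers with a few OVER-averse walkers reproduces the
#: standard protocol's trial-count arithmetic for a 13-participant cohort.
DEFAULT_THRESHOLDS = (
    -0.25, 0.0, -0.25, 0.0, -0.25, 0.85, 0.0, -0.25, 0.0, -0.25, 1.55, 0.0, -0.25,
)


class ThresholdChoiceModel:
    """Deterministic choice: OVER whenever the predicted advantage exceeds a
    per-participant threshold."""

    def __init__(self, thresholds=DEFAULT_THRESHOLDS):
        self.thresholds = tuple(thresholds)

    def choose(self, participant_index: int, advantage: float, rng=None) -> str:
        tau = self.thresholds[participant_index % len(self.thresholds)]
        return "OVER" if advantage > tau else "IN"


class LogisticChoiceModel:
    """Stochastic choice: P(OVER) = expit(b0 + b1 * advantage)."""

    def __init__(self, b0: float, b1: float):
        if not (np.isfinite(b0) and np.isfinite(b1)):
            raise ValueError("b0 and b1 must be finite")
        self.b0, self.b1 = float(b0), float(b1)

    def choose(self, participant_index: int, advantage: float, rng) -> str:
        p = expit(self.b0 + self.b1 * advantage)
        return "OVER" if rng.random() < p else "IN"


def _model_advantage(depth_rel: float, length_rel: float) -> float:
    """Predicted OVER cost advantage from the forward cost model defaults."""
    from .cost_model import CostFunctionParams, predict_in_cost, predict_over_cost

    cp = CostFunctionParams()
    return predict_in_cost(depth_rel, cp) - predict_over_cost(length_rel, cp)


def generate_session(
    participants: list[Participant],
    grid: list[tuple[float, float]] | None = None,
    seed: int = 0,
    n_dropout: int = 0,
    choice_model=None,
    params: GeneratorParams | None = None,
    generate_markers: bool = True,
    speed_mean: float = 1.3,
    speed_sd: float = 0.1,
):
    """Generate a full experimental session.

    Per participant: 25 preferred-condition trials (one per geometry, with
    the traversal strategy drawn from ``choice_model``) plus enforced
    non-preferred trials, reduced per protocol: no repeated enforced OVER at
    a length already crossed OVER, and one enforced OVER at the greatest
    depth for each length never crossed OVER.  ``n_dropout`` trials (chosen
    at random) carry a marker dropout interval.

    Returns a list of ``(TrialSpec, MarkerTrajectorySet | None)`` pairs.
    """
    if not participants:
        raise ValueError("participant list is empty")
    grid = grid if grid is not None else standard_grid()
    depths = sorted({d for d, _ in grid})
    lengths = sorted({ln for _, ln in grid})
    if len(grid) != len(depths) * len(lengths):
        raise ValueError("grid must be a full depths x lengths product")
    choice_model = choice_model or ThresholdChoiceModel()
    rng = np.random.default_rng(seed)

    specs: list[TrialSpec] = []
    for pi, part in enumerate(participants):
        chosen: dict[tuple[float, float], str] = {}
        # preferred trials, one per geometry in randomized order
        order = list(grid)
        rng.shuffle(order)
        for d, ln in order:
            adv = _model_advantage(d, ln)
            strat = choice_model.choose(pi, adv, rng)
            chosen[(d, ln)] = strat
            specs.append(
                TrialSpec(
                    participant=part,
                    obstacle=Obstacle(d, ln, part.leg_length),
                    strategy=strat,
                    condition="preferred",
                    approach_speed_target=float(
                        max(rng.normal(speed_mean, speed_sd), 0.6)
                    ),
                    steps_in_base=1 if strat == "IN" else 0,
                    seed=int(rng.integers(2**31)),
                    trial_id=f"P{pi:02d}_pref_d{d:g}_l{ln:g}",
                )
            )
        # enforced trials with the protocol's OVER reduction rules
        for ln in lengths:
            over_depths = [d for d in depths if chosen[(d, ln)] == "OVER"]
            if over_depths:
                enforced = [(d, "IN") for d in over_depths]
            else:
                enforced = [(max(depths), "OVER")]
            for d, strat in enforced:
                specs.append(
                    TrialSpec(
                        participant=part,
                        obstacle=Obstacle(d, ln, part.leg_length),
                        strategy=strat,
                        condition="enforced",
                        approach_speed_target=float(
                            max(rng.normal(speed_mean, speed_sd), 0.6)
                        ),
                        steps_in_base=1 if strat == "IN" else 0,
                        seed=int(rng.integers(2**31)),
                        trial_id=f"P{pi:02d}_enf_d{d:g}_l{ln:g}",
                    )
                )

    if n_dropout > len(specs):
        raise ValueError("more dropout trials requested than trials in session")
    drop_idx = rng.choice(len(specs), size=n_dropout, replace=False) if n_dropout else []
    from .types import MARKER_LABELS

    for i in drop_idx:
        label = MARKER_LABELS[int(rng.integers(len(MARKER_LABELS)))]
        specs[i] = replace(specs[i], dropout=(label, 300, 360))

    out = []
    for sp in specs:
        mset = generate_trial_markers(sp, params) if generate_markers else None
        out.append((sp, mset))
    return out


def generate_choice_dataset(
    b0: float, b1: float, x_values, n_per_x: int, seed: int = 0
):
    """Binary OVER/IN choices drawn from the logistic choice law.

    Returns a pandas DataFrame with columns ``x`` and ``chose_over``; the
    generating coefficients are stored in ``df.attrs``.
    """
    import pandas as pd

    if not (np.isfinite(b0) and np.isfinite(b1)):
        raise ValueError("b0 and b1 must be finite")
    if n_per_x < 1:
        raise ValueError("n_per_x must be >= 1")
    x_values = np.asarray(x_values, dtype=float)
    if not np.all(np.isfinite(x_values)):
        raise ValueError("x values must be finite")
    rng = np.random.default_rng(seed)
    x = np.repeat(x_values, n_per_x)
    prob = expit(b0 + b1 * x)
    chose = rng.random(len(x)) < prob
    df = pd.DataFrame({"x": x, "chose_over": chose})
    df.attrs["generating_params"] = (float(b0), float(b1))
    return df
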