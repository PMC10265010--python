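"""Marker filtering, gait event detection, step segmentation and traversal
identification.

Stance phases are detected from the horizontal speed of the foot markers
(fifth metatarsal head and lateral malleolus): a stance is a maximal run in
which both markers move slower than a fraction of the trial's mean forward
speed for at least a minimum duration, with edges refined against a tighter
near-stationarity threshold.  A step runs from the start of one stance phase
to the frame before the start of the contralateral stance phase.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .types import GRAVITY, GaitEvent, MarkerTrajectorySet, Obstacle, Step, Traversal

__all__ = [
    "lowpass_filter",
    "detect_stance_phases",
    "segment_steps",
    "identify_traversal",
    "froude",
    "mean_forward_speed",
    "MissingMarkerError",
]


class MissingMarkerError(KeyError):
    """A marker required by the operation is absent or has gaps."""


#: Corner-frequency correction for a dual-pass (forward-backward) 2nd-order
#: Butterworth so the effective 4th-order zero-phase response is -3 dB at the
#: nominal corner: (2**0.5 - 1) ** -0.25.
_DUAL_PASS_CORRECTION = (2.0**0.5 - 1.0) ** -0.25


def lowpass_filter(
    markers: MarkerTrajectorySet, corner_hz: float = 6.0
) -> MarkerTrajectorySet:
    """Fourth-order zero-phase Butterworth low-pass filter of all markers.

    Realized as a 2nd-order filter applied forward then backward (zero net
    phase shift, effective 4th-order magnitude response) with the standard
    dual-pass corner correction, so a unit sinusoid at the corner frequency
    is attenuated to 1/sqrt(2).
    """
    fs = markers.frame_rate
    nyq = fs / 2.0
    design = corner_hz * _DUAL_PASS_CORRECTION
    if corner_hz >= nyq or design >= nyq:
        raise ValueError(f"corner {corner_hz} Hz too close to Nyquist ({nyq} Hz)")
    b, a = butter(2, design / nyq)
    out = {}
    for label, arr in markers.markers.items():
        if np.isnan(arr).any():
            raise MissingMarkerError(
                f"marker {label!r} has missing samples; run QC before filtering"
            )
        out[label] = filtfilt(b, a, arr, axis=0)
    return MarkerTrajectorySet(fs, out, markers.participant, dict(markers.meta))


def _horizontal_speed(arr: np.ndarray, fps: float) -> np.ndarray:
    """Per-frame horizontal (x, y) speed by central differences (one-sided at
    the ends)."""
    vel = np.gradient(arr[:, :2], 1.0 / fps, axis=0)
    return np.hypot(vel[:, 0], vel[:, 1])


def mean_forward_speed(markers: MarkerTrajectorySet) -> float:
    """Net forward (+x) displacement of the mid-hip point over the trial
    duration."""
    mid = 0.5 * (markers["L_HIP"][:, 0] + markers["R_HIP"][:, 0])
    duration = (markers.n_frames - 1) / markers.frame_rate
    return float((mid[-1] - mid[0]) / duration)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_stance_phases(
    markers: MarkerTrajectorySet,
    side: str,
    threshold_frac: float = 0.20,
    refine_frac: float = 0.05,
    min_duration: float = 0.10,
) -> list[GaitEvent]:
    """Detect stance phases of one foot from foot-marker horizontal speed.

    A stance is a maximal run where both the metatarsal and the malleolus
    markers are slower than ``threshold_frac`` of the trial's mean forward
    speed for at least ``min_duration`` seconds; run edges are then refined
    to the frames where both speeds fall below ``refine_frac`` of the mean
    forward speed.  Returns alternating stance_start / stance_end events
    (half-open frame convention).  An empty list means no stance was found
    and the trial should be flagged.
    """
    prefix = "L" if side == "left" else "R"
    fps = markers.frame_rate
    speeds = []
    for name in ("MT5", "ANK"):
        label = f"{prefix}_{name}"
        if label not in markers.markers:
            raise MissingMarkerError(f"marker {label!r} required for stance detection")
        arr = markers[label]
        if np.isnan(arr).any():
            raise MissingMarkerError(f"marker {label!r} has missing samples")
        speeds.append(_horizontal_speed(arr, fps))
    speed = np.maximum(*speeds)

    vbar = abs(mean_forward_speed(markers))
    if vbar <= 0:
        raise ValueError("non-positive mean forward speed")
    coarse = speed < threshold_frac * vbar
    tight = speed < refine_frac * vbar
    min_frames = max(int(round(min_duration * fps)), 1)

    events: list[GaitEvent] = []
    for a, b in _runs(coarse):
        if b - a < min_frames:
            continue
        inside = np.flatnonzero(tight[a:b])
        if inside.size:
            a2, b2 = a + inside[0], a + inside[-1] + 1
            if b2 - a2 >= min_frames:
                a, b = a2, b2
        events.append(GaitEvent("stance_start", side, int(a)))
        events.append(GaitEvent("stance_end", side, int(b)))
    return events


def _stance_intervals(events: list[GaitEvent]) -> list[tuple[int, int]]:
    starts = [e.frame for e in events if e.kind == "stance_start"]
    ends = [e.frame for e in events if e.kind == "stance_end"]
    if len(starts) != len(ends):
        raise ValueError("stance starts and ends do not alternate")
    out = list(zip(starts, ends))
    for (a, b) in out:
        if b <= a:
            raise ValueError("stance end precedes its start")
    return out


def segment_steps(
    events_left: list[GaitEvent],
    events_right: list[GaitEvent],
    markers: MarkerTrajectorySet,
) -> list[Step]:
    """Cut the trial into steps at stance starts.

    Each step spans [stance_start(side), stance_start(contralateral)) and its
    length is the horizontal distance between the malleolus positions of the
    two flanking footfalls, each taken at its own stance-phase midpoint
    (midpoints are robust to event-edge jitter).
    """
    stances = [
        (a, b, "left") for a, b in _stance_intervals(events_left)
    ] + [(a, b, "right") for a, b in _stance_intervals(events_right)]
    if not stances:
        return []
    stances.sort(key=lambda s: (s[0], -s[1]))

    # quiet standing (e.g. at the start of a trial) gives both sides a stance
    # starting together (exactly, or a few frames apart under noise); the foot
    # that swings first contributes no step boundary.  Drop a stance when it
    # is contained in a longer opposite-side stance starting near-
    # simultaneously (within the minimum stance duration).  Genuine landings
    # start much later into the opposite stance and are kept.
    tol = int(round(0.10 * markers.frame_rate))

    def is_standing_tie(s, o):
        return (
            o[0] <= s[0] <= o[0] + tol
            and s[1] <= o[1]
            and (o[1] - o[0]) > (s[1] - s[0])
        )

    by_side = {
        "left": _stance_intervals(events_left),
        "right": _stance_intervals(events_right),
    }
    merged: list[tuple[int, int, str]] = []
    for st in stances:
        other = by_side["left" if st[2] == "right" else "right"]
        if any(is_standing_tie(st, o) for o in other):
            continue
        if merged and st[0] == merged[-1][0]:
            continue  # sorted so the longer stance comes first
        merged.append(st)

    for prev, cur in zip(merged, merged[1:]):
        if prev[2] == cur[2]:
            raise ValueError(
                f"two consecutive {cur[2]} stance starts at frames "
                f"{prev[0]} and {cur[0]}: missed contralateral event"
            )

    fps = markers.frame_rate

    def footfall(stance):
        a, b, side = stance
        mid = (a + b) // 2
        ank = markers["L_ANK" if side == "left" else "R_ANK"]
        return float(ank[mid, 0]), float(ank[mid, 2])

    steps: list[Step] = []
    for cur, nxt in zip(merged, merged[1:]):
        p0, p1 = footfall(cur), footfall(nxt)
        start, end = cur[0], nxt[0]
        steps.append(
            Step(
                side=cur[2],
                start_frame=start,
                end_frame=end,
                length=abs(p1[0] - p0[0]),
                duration=(end - start) / fps,
                start_pos=p0,
                end_pos=p1,
            )
        )
    return steps


def identify_traversal(
    steps: list[Step],
    obstacle: Obstacle,
    obstacle_span: tuple[float, float],
    strategy: str,
) -> Traversal:
    """Select the steps that constitute the obstacle traversal.

    IN: all steps from the lead-leg step down into the base to the step that
    returns the trail leg to the raised trackway (inclusive), so base
    placements add steps.  OVER: exactly the lead and trail crossing steps.
    The approach step is three steps before the first traversal step.
    """
    if not steps:
        raise ValueError("no steps to search for a traversal")
    x0, x1 = obstacle_span
    # footfall sequence: start of the first step then every landing
    footfalls = [steps[0].start_pos] + [s.end_pos for s in steps]
    flags: list[str] = []

    if strategy == "IN":
        rim_z = float(np.median([p[1] for p in footfalls[:3]]))
        base = [
            m
            for m, (x, z) in enumerate(footfalls)
            if x0 < x < x1 and z < rim_z - 0.4 * obstacle.depth_abs
        ]
        if not base:
            raise ValueError("IN strategy but no footfall found in the obstacle base")
        first, last = min(base) - 1, max(base) + 1
    elif strategy == "OVER":
        cross = [
            m
            for m in range(len(footfalls) - 1)
            if footfalls[m][0] <= x0 and footfalls[m + 1][0] >= x1
        ]
        if not cross:
            raise ValueError("OVER strategy but no step spans the obstacle")
        first, last = cross[0], cross[0] + 1
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    if first < 0 or last >= len(steps):
        raise ValueError("traversal extends beyond the recorded steps")

    approach = None
    if first - 3 >= 0:
        approach = steps[first - 3]
    else:
        flags.append("approach_undefined")

    return Traversal(
        strategy=strategy,  # type: ignore[arg-type]
        steps=steps[first : last + 1],
        approach_step=approach,
        obstacle=obstacle,
        first_step_index=first,
        flags=flags,
    )


def froude(speed: float, leg_length: float) -> float:
    """Dimensionless walking speed Fr = v / sqrt(g * l), g = 9.81 m s^-2."""
    if leg_length <= 0:
        raise ValueError("leg length must be positive")
    return speed / np.sqrt(GRAVITY * leg_length)
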