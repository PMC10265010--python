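"""Core domain types shared across the pipeline.

Coordinate convention used everywhere: +x is the walking direction, +z is
vertical (up), units are metres and seconds, frame 0 is the start of the
trial, and frame intervals are half-open ``[start, end)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Strategy = Literal["IN", "OVER"]
Condition = Literal["preferred", "enforced"]
Side = Literal["left", "right"]

#: Gravitational acceleration used throughout (m s^-2).
GRAVITY = 9.81

#: Marker labels: 7 anatomical landmarks per side.
#: MT5 = head of the fifth metatarsal, ANK = lateral malleolus,
#: KNEE = lateral femoral condyle, HIP = greater trochanter,
#: SHO = acromioclavicular joint, ELB = humeral lateral epicondyle,
#: WRI = radial dorsal tubercle.
MARKER_LABELS = tuple(
    f"{side}_{name}"
    for side in ("L", "R")
    for name in ("MT5", "ANK", "KNEE", "HIP", "SHO", "ELB", "WRI")
)


@dataclass(frozen=True)
class Participant:
    """One walker: body mass in kg and leg length (standing greater
    trochanter height) in metres."""

    id: str
    mass: float
    leg_length: float

    def __post_init__(self) -> None:
        if not (self.mass > 0):
            raise ValueError(f"mass must be positive, got {self.mass}")
        if not (self.leg_length > 0):
            raise ValueError(f"leg_length must be positive, got {self.leg_length}")


@dataclass(frozen=True)
class Obstacle:
    """A cuboidal hole spanning the trackway, sized relative to leg length."""

    depth_rel: float
    length_rel: float
    leg_length: float

    def __post_init__(self) -> None:
        if self.depth_rel < 0 or self.length_rel <= 0:
            raise ValueError("obstacle dimensions must be non-negative / positive")

    @property
    def depth_abs(self) -> float:
        return self.depth_rel * self.leg_length

    @property
    def length_abs(self) -> float:
        return self.length_rel * self.leg_length


#: The standard experimental grid of relative obstacle sizes.
DEPTH_GRID = (0.1, 0.2, 0.3, 0.4, 0.5)
LENGTH_GRID = (0.5, 0.65, 0.8, 0.95, 1.1)


def standard_grid() -> list[tuple[float, float]]:
    """All (depth_rel, length_rel) combinations of the standard 5 x 5 grid."""
    return [(d, ln) for d in DEPTH_GRID for ln in LENGTH_GRID]


@dataclass(frozen=True)
class TrialSpec:
    """Specification of one synthetic walking trial."""

    participant: Participant
    obstacle: Obstacle
    strategy: Strategy
    condition: Condition = "preferred"
    approach_speed_target: float = 1.3
    steps_in_base: int = 0  # foot placements in the base; 0 for OVER, >=1 for IN
    dropout: tuple[str, int, int] | None = None  # (marker label, start frame, end frame)
    seed: int = 0
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.strategy == "OVER" and self.steps_in_base != 0:
            raise ValueError("steps_in_base must be 0 for OVER trials")
        if self.strategy == "IN" and self.steps_in_base < 1:
            raise ValueError("IN trials require at least one foot placement in the base")
        if self.approach_speed_target <= 0:
            raise ValueError("approach speed must be positive")


class MarkerTrajectorySet:
    """Time-indexed 3-D positions of named markers for one trial.

    Missing samples (marker dropout) are stored as NaN rows and exposed via
    :meth:`missing`; they are never silently zero.
    """

    def __init__(
        self,
        frame_rate: float,
        markers: dict[str, np.ndarray],
        participant: Participant,
        meta: dict | None = None,
    ):
        if frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        lengths = {len(v) for v in markers.values()}
        if len(lengths) > 1:
            raise ValueError("all marker sequences must have equal length")
        self.frame_rate = float(frame_rate)
        self.markers = {k: np.asarray(v, dtype=float) for k, v in markers.items()}
        self.participant = participant
        self.meta = dict(meta or {})

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.markers.values())))

    @property
    def labels(self) -> list[str]:
        return list(self.markers)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.markers[label]
        except KeyError:
            raise KeyError(f"marker {label!r} not present (have {sorted(self.markers)})")

    def missing(self, label: str) -> np.ndarray:
        """Boolean per-frame mask of missing samples for one marker."""
        return np.isnan(self[label]).any(axis=1)

    def has_gaps(self, labels=None) -> bool:
        labels = labels if labels is not None else self.labels
        return any(self.missing(lb).any() for lb in labels)

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            self.frame_rate,
            {k: v.copy() for k, v in self.markers.items()},
            self.participant,
            dict(self.meta),
        )


@dataclass(frozen=True)
class GaitEvent:
    kind: Literal["stance_start", "stance_end"]
    side: Side
    frame: int


@dataclass
class Step:
    """One step: stance start of one foot to the frame before the
    contralateral stance start (half-open frame interval)."""

    side: Side
    start_frame: int
    end_frame: int
    length: float
    duration: float
    start_pos: tuple[float, float]  # (x, z) of the starting foot's stance-midpoint malleolus
    end_pos: tuple[float, float]    # (x, z) of the landing foot's stance-midpoint malleolus

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("step duration must be positive")

    @property
    def speed(self) -> float:
        return self.length / self.duration

    def froude(self, leg_length: float) -> float:
        from .kinematics import froude as _froude

        return _froude(self.speed, leg_length)


@dataclass
class Traversal:
    """The ordered steps of one obstacle crossing plus the approach step."""

    strategy: Strategy
    steps: list[Step]
    approach_step: Step | None
    obstacle: Obstacle
    first_step_index: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def distance(self) -> float:
        return float(sum(s.length for s in self.steps))

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.steps))

    @property
    def speed(self) -> float:
        return self.distance / self.duration


@dataclass
class WorkBreakdown:
    """Positive mechanical work over one window (a step or whole task), J."""

    w_com: float
    w_int: float
    distance: float

    @property
    def w_tot(self) -> float:
        return self.w_com + self.w_int


@dataclass
class StepCost:
    step: Step
    work: WorkBreakdown
    cot_tot: float
    cot_com: float


@dataclass
class CostOfTransport:
    """Mass- and distance-normalised cost for a traversal task, J kg^-1 m^-1."""

    cot_tot: float
    cot_com: float
    steps: list[StepCost]
    work: WorkBreakdown
    mass: float

    @property
    def step_fractions_tot(self) -> np.ndarray:
        w = np.array([s.work.w_tot for s in self.steps])
        return w / w.sum()
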