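"""Anthropometric segment parameters for the 11-segment body model.

The model comprises head+trunk, and left/right upper arms, forearms
(including the hand mass), thighs, shanks and feet, each defined by a
proximal and a distal marker.  Default relative masses and centre-of-mass
locations are Winter's standard cadaver-derived values; any table satisfying
the invariants (relative masses summing to 1, fractions in (0, 1)) may be
substituted via :func:`load_table`.

Segment kinetic energy is translational by default; rotational energy
(1/2 m (k L)^2 w^2 with k the radius-of-gyration fraction) is added only
when ``include_rotational`` is enabled on a table that carries gyration
fractions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Each segment: (proximal marker, distal marker). Virtual markers MID_SHO /
# MID_HIP are the midpoints of the two acromion / trochanter markers.
SEGMENT_ENDPOINTS: dict[str, tuple[str, str]] = {
    "head_trunk": ("MID_SHO", "MID_HIP"),
    "L_upper_arm": ("L_SHO", "L_ELB"),
    "R_upper_arm": ("R_SHO", "R_ELB"),
    "L_forearm": ("L_ELB", "L_WRI"),
    "R_forearm": ("R_ELB", "R_WRI"),
    "L_thigh": ("L_HIP", "L_KNEE"),
    "R_thigh": ("R_HIP", "R_KNEE"),
    "L_shank": ("L_KNEE", "L_ANK"),
    "R_shank": ("R_KNEE", "R_ANK"),
    "L_foot": ("L_ANK", "L_MT5"),
    "R_foot": ("R_ANK", "R_MT5"),
}

# Energy pools for internal work: kinetic/potential exchange is allowed
# within a limb (or the trunk) but not between pools.
ENERGY_POOLS: dict[str, tuple[str, ...]] = {
    "trunk": ("head_trunk",),
    "left_arm": ("L_upper_arm", "L_forearm"),
    "right_arm": ("R_upper_arm", "R_forearm"),
    "left_leg": ("L_thigh", "L_shank", "L_foot"),
    "right_leg": ("R_thigh", "R_shank", "R_foot"),
}

# Winter's segment parameters: mass fraction of body mass, CoM location as a
# fraction of segment length from the proximal endpoint, radius of gyration
# about the CoM as a fraction of segment length. Forearm row is forearm+hand.
_DEFAULT_ROWS = {
    # segment base name: (relative mass, com fraction, gyration fraction)
    "head_trunk": (0.578, 0.40, 0.503),
    "upper_arm": (0.028, 0.436, 0.322),
    "forearm": (0.022, 0.682, 0.468),
    "thigh": (0.100, 0.433, 0.323),
    "shank": (0.0465, 0.433, 0.302),
    "foot": (0.0145, 0.50, 0.475),
}


@dataclass(frozen=True)
class SegmentParams:
    relative_mass: float
    com_fraction: float
    gyration_fraction: float | None = None


@dataclass
class AnthropometricTable:
    segments: dict[str, SegmentParams] = field(default_factory=dict)
    include_rotational: bool = False

    def __post_init__(self) -> None:
        missing = set(SEGMENT_ENDPOINTS) - set(self.segments)
        if missing:
            raise ValueError(f"anthropometric table missing segments: {sorted(missing)}")
        total = sum(p.relative_mass for p in self.segments.values())
        if abs(total - 1.0) > 0.005:
            raise ValueError(f"segment relative masses sum to {total:.4f}, expected 1")
        for name, p in self.segments.items():
            if not (0 < p.relative_mass < 1) or not (0 < p.com_fraction < 1):
                raise ValueError(f"fractions for {name} must lie in (0, 1)")
        if self.include_rotational and any(
            p.gyration_fraction is None for p in self.segments.values()
        ):
            raise ValueError("rotational energy requested but gyration fractions missing")


def default_table(include_rotational: bool = False) -> AnthropometricTable:
    """The shipped default table (Winter's values, hand folded into forearm)."""
    segments: dict[str, SegmentParams] = {}
    for seg in SEGMENT_ENDPOINTS:
        base = seg.split("_", 1)[1] if seg[:2] in ("L_", "R_") else seg
        m, c, k = _DEFAULT_ROWS[base]
        segments[seg] = SegmentParams(m, c, k)
    return AnthropometricTable(segments, include_rotational=include_rotational)


def save_table(table: AnthropometricTable, path) -> None:
    """Write a table as a plain-text key-value config (one segment per line)."""
    with open(path, "w") as fh:
        fh.write("# segment\trelative_mass\tcom_fraction\tgyration_fraction\n")
        for name, p in table.segments.items():
            gyr = "" if p.gyration_fraction is None else f"{p.gyration_fraction:.6g}"
            fh.write(f"{name}\t{p.relative_mass:.6g}\t{p.com_fraction:.6g}\t{gyr}\n")


def load_table(path, include_rotational: bool = False) -> AnthropometricTable:
    segments: dict[str, SegmentParams] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name, mass, com = parts[0], float(parts[1]), float(parts[2])
            gyr = float(parts[3]) if len(parts) > 3 and parts[3] else None
            segments[name] = SegmentParams(mass, com, gyr)
    return AnthropometricTable(segments, include_rotational=include_rotational)


def segment_masses(table: AnthropometricTable, body_mass: float) -> dict[str, float]:
    return {name: p.relative_mass * body_mass for name, p in table.segments.items()}
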