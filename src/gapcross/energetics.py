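"""Centre-of-mass and segmental mechanical energy, positive-increment work,
and cost of transport.

An 11-segment model (head+trunk, upper arms, forearms, thighs, shanks, feet)
is assembled from the 14 markers.  Whole-body CoM work is the sum of
positive increments of the CoM's kinetic plus gravitational potential
energy.  Internal work sums positive increments of five energy pools (each
arm, each leg, head+trunk) evaluated in the CoM-relative frame, so kinetic /
potential exchange is permitted within a limb but not between limbs.  Total
work is their sum by construction.

Vertical datum is the trackway surface (z = 0); positive-increment work is
invariant to this choice.  Velocities are central differences on (filtered)
positions, one-sided at the series ends.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .anthro import ENERGY_POOLS, SEGMENT_ENDPOINTS, AnthropometricTable, default_table
from .types import (
    GRAVITY,
    CostOfTransport,
    MarkerTrajectorySet,
    StepCost,
    Traversal,
    WorkBreakdown,
)

__all__ = [
    "BodyModel",
    "com_trajectory",
    "positive_increment_work",
    "internal_work",
    "cost_of_transport",
    "traversal_energetics",
]


def _velocity(pos: np.ndarray, fps: float) -> np.ndarray:
    return np.gradient(pos, 1.0 / fps, axis=0)


def _resolve_endpoint(markers: MarkerTrajectorySet, name: str) -> np.ndarray:
    if name == "MID_SHO":
        return 0.5 * (markers["L_SHO"] + markers["R_SHO"])
    if name == "MID_HIP":
        return 0.5 * (markers["L_HIP"] + markers["R_HIP"])
    return markers[name]


@dataclass
class BodyModel:
    """Per-frame segment CoM positions/velocities and the whole-body CoM."""

    frame_rate: float
    mass: float
    segment_masses: dict[str, float]
    segment_com: dict[str, np.ndarray]       # (n, 3) positions
    segment_vel: dict[str, np.ndarray]
    segment_rot_energy: dict[str, np.ndarray] | None
    com: np.ndarray                          # (n, 3) whole-body CoM
    com_vel: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.com)

    def com_energy(self) -> np.ndarray:
        """Whole-body CoM mechanical energy (kinetic + gravitational), J."""
        ke = 0.5 * self.mass * np.sum(self.com_vel**2, axis=1)
        pe = self.mass * GRAVITY * self.com[:, 2]
        return ke + pe

    def pool_energies(self) -> dict[str, np.ndarray]:
        """Energy of each limb/trunk pool in the CoM-relative frame, J."""
        out: dict[str, np.ndarray] = {}
        for pool, segs in ENERGY_POOLS.items():
            e = np.zeros(self.n_frames)
            for seg in segs:
                m = self.segment_masses[seg]
                rel_v = self.segment_vel[seg] - self.com_vel
                rel_z = self.segment_com[seg][:, 2] - self.com[:, 2]
                e += 0.5 * m * np.sum(rel_v**2, axis=1) + m * GRAVITY * rel_z
                if self.segment_rot_energy is not None:
                    e += self.segment_rot_energy[seg]
            out[pool] = e
        return out


def com_trajectory(
    markers: MarkerTrajectorySet,
    anthropometry: AnthropometricTable | None = None,
) -> BodyModel:
    """Assemble the 11-segment model and the mass-weighted whole-body CoM.

    Segment CoMs are interpolated along the proximal-to-distal marker chord
    at the tabulated fraction.  Requires all 14 markers gap-free and the
    participant's body mass.
    """
    table = anthropometry or default_table()
    mass = markers.participant.mass
    fps = markers.frame_rate

    seg_com: dict[str, np.ndarray] = {}
    seg_vel: dict[str, np.ndarray] = {}
    seg_rot: dict[str, np.ndarray] | None = {} if table.include_rotational else None
    seg_mass = {name: p.relative_mass * mass for name, p in table.segments.items()}

    for seg, (prox_name, dist_name) in SEGMENT_ENDPOINTS.items():
        prox = _resolve_endpoint(markers, prox_name)
        dist = _resolve_endpoint(markers, dist_name)
        for name, arr in ((prox_name, prox), (dist_name, dist)):
            if np.isnan(arr).any():
                raise ValueError(f"marker {name!r} has missing samples in {seg}")
        frac = table.segments[seg].com_fraction
        com = prox + frac * (dist - prox)
        seg_com[seg] = com
        seg_vel[seg] = _velocity(com, fps)
        if seg_rot is not None:
            chord = dist - prox
            length = np.linalg.norm(chord, axis=1)
            unit = chord / np.maximum(length[:, None], 1e-9)
            dunit = _velocity(unit, fps)
            omega_sq = np.sum(dunit**2, axis=1)  # |du/dt| = |w x u| for unit u
            k = table.segments[seg].gyration_fraction
            seg_rot[seg] = 0.5 * seg_mass[seg] * (k * length) ** 2 * omega_sq

    com = sum(seg_mass[s] * seg_com[s] for s in seg_com) / mass
    com_vel = _velocity(com, fps)
    return BodyModel(fps, mass, seg_mass, seg_com, seg_vel, seg_rot, com, com_vel)


def positive_increment_work(
    energy: np.ndarray, window: tuple[int, int] | None = None
) -> float:
    """Sum of positive frame-to-frame energy increments over a half-open
    frame window.

    The increment between frames t and t+1 belongs to the window containing
    t, so work is additive over a partition of a window.
    """
    energy = np.asarray(energy, dtype=float)
    a, b = window if window is not None else (0, len(energy) - 1)
    if b <= a:
        warnings.warn("empty work window; returning 0", stacklevel=2)
        return 0.0
    hi = min(b, len(energy) - 1)
    inc = np.diff(energy[a : hi + 1])
    return float(np.sum(inc[inc > 0]))


def internal_work(
    model: BodyModel, window: tuple[int, int] | None = None
) -> float:
    """Internal work: positive increments of each limb/trunk pool energy in
    the CoM-relative frame, rectified per pool and summed across pools."""
    return float(
        sum(positive_increment_work(e, window) for e in model.pool_energies().values())
    )


def com_work(model: BodyModel, window: tuple[int, int] | None = None) -> float:
    return positive_increment_work(model.com_energy(), window)


def work_breakdown(
    model: BodyModel, window: tuple[int, int], distance: float
) -> WorkBreakdown:
    return WorkBreakdown(
        w_com=com_work(model, window),
        w_int=internal_work(model, window),
        distance=distance,
    )


def cost_of_transport(work: WorkBreakdown, mass: float, distance: float | None = None):
    """Mass- and distance-specific cost, J kg^-1 m^-1 (total and CoM-only)."""
    distance = work.distance if distance is None else distance
    if mass <= 0:
        raise ValueError("mass must be positive")
    if distance <= 0:
        raise ValueError("distance must be positive")
    return work.w_tot / (mass * distance), work.w_com / (mass * distance)


def traversal_energetics(
    markers: MarkerTrajectorySet,
    traversal: Traversal,
    anthropometry: AnthropometricTable | None = None,
    model: BodyModel | None = None,
) -> CostOfTransport:
    """Per-step and whole-task work and cost of transport for a traversal.

    Task distance is the sum of traversal step lengths and task work the sum
    of per-step work (windows tile the task), so per-step work fractions sum
    to one.
    """
    model = model if model is not None else com_trajectory(markers, anthropometry)
    mass = markers.participant.mass

    step_costs: list[StepCost] = []
    for step in traversal.steps:
        wb = work_breakdown(model, (step.start_frame, step.end_frame), step.length)
        cot_tot, cot_com = cost_of_transport(wb, mass)
        step_costs.append(StepCost(step, wb, cot_tot, cot_com))

    task = WorkBreakdown(
        w_com=sum(s.work.w_com for s in step_costs),
        w_int=sum(s.work.w_int for s in step_costs),
        distance=sum(s.work.distance for s in step_costs),
    )
    cot_tot, cot_com = cost_of_transport(task, mass)
    return CostOfTransport(cot_tot, cot_com, step_costs, task, mass)
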