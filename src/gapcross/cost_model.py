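"""Forward model of predicted metabolic cost of transport for the two
hole-crossing strategies, and the equal-cost boundary over the obstacle
depth x length grid.

The OVER strategy pays a convex (quadratic by default) penalty in the step
length extension required to span the hole without changing walking speed;
it is independent of hole depth.  The IN strategy pays linearly for stepping
down and stepping up through the hole depth, the upward component dominating
(c_up > c_down); it is independent of hole length.

The published empirical coefficients behind these cost functions are not
reproduced here; the shipped defaults are calibration placeholders with the
stated functional forms and qualitative structure (costs >= baseline at zero
perturbation, surfaces intersecting within the standard grid).  Substitute
measured coefficients via :class:`CostFunctionParams` for quantitative use.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import DEPTH_GRID, LENGTH_GRID

__all__ = [
    "CostFunctionParams",
    "CostSurface",
    "predict_over_cost",
    "predict_in_cost",
    "evaluate_surfaces",
    "strategy_boundary",
]


@dataclass(frozen=True)
class CostFunctionParams:
    """Coefficients of the forward cost functions (J kg^-1 m^-1 scale).

    baseline_cot: level walking at the preferred step length.
    over_quadratic: penalty per unit squared relative step-length extension.
    c_down / c_up: cost per unit relative hole depth of the downward and
    upward steps; c_up > c_down > 0.
    preferred_step_length_rel: preferred step length as a fraction of leg
    length.
    max_step_length_rel: longest feasible crossing step (fraction of leg
    length); required steps beyond it are flagged infeasible.
    """

    baseline_cot: float = 2.5
    over_quadratic: float = 10.0
    c_down: float = 1.0
    c_up: float = 4.0
    preferred_step_length_rel: float = 0.75
    max_step_length_rel: float = 1.5

    def __post_init__(self) -> None:
        if self.baseline_cot <= 0:
            raise ValueError("baseline cost must be positive")
        if not (self.c_up > self.c_down > 0):
            raise ValueError("require c_up > c_down > 0")
        if self.over_quadratic < 0:
            raise ValueError("convex penalty coefficient must be non-negative")


def predict_over_cost(length_rel, params: CostFunctionParams | None = None):
    """Predicted cost of stepping across a hole of given relative length.

    The required step length equals the hole length; the cost is the
    baseline plus a quadratic penalty in the relative extension beyond the
    preferred step length.  Independent of depth.  Raises if the required
    step exceeds the feasible maximum.
    """
    p = params or CostFunctionParams()
    length_rel = np.asarray(length_rel, dtype=float)
    if np.any(length_rel < 0):
        raise ValueError("length must be non-negative")
    if np.any(length_rel > p.max_step_length_rel):
        raise ValueError(
            f"required step length exceeds feasible maximum "
            f"({p.max_step_length_rel} leg lengths): infeasible OVER"
        )
    ext = np.maximum(0.0, length_rel - p.preferred_step_length_rel) / (
        p.preferred_step_length_rel
    )
    out = p.baseline_cot + p.over_quadratic * ext**2
    return float(out) if out.ndim == 0 else out


def predict_in_cost(depth_rel, params: CostFunctionParams | None = None):
    """Predicted cost of stepping down into and back up out of a hole of
    given relative depth: baseline plus linear down- and up-step components,
    the upward one larger.  Independent of length."""
    p = params or CostFunctionParams()
    depth_rel = np.asarray(depth_rel, dtype=float)
    if np.any(depth_rel < 0):
        raise ValueError("depth must be non-negative")
    out = p.baseline_cot + (p.c_down + p.c_up) * depth_rel
    return float(out) if out.ndim == 0 else out


@dataclass
class CostSurface:
    """Predicted cost per strategy on a (depth, length) grid."""

    depths: np.ndarray
    lengths: np.ndarray
    over: np.ndarray  # (n_depth, n_length)
    in_: np.ndarray
    params: CostFunctionParams = field(default_factory=CostFunctionParams)

    @property
    def lower_cost_labels(self) -> np.ndarray:
        """Grid labels of the lower-cost strategy ('OVER' / 'IN')."""
        return np.where(self.over <= self.in_, "OVER", "IN")

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, d in enumerate(self.depths):
            for j, ln in enumerate(self.lengths):
                rows.append((d, ln, "OVER", self.over[i, j]))
                rows.append((d, ln, "IN", self.in_[i, j]))
        return pd.DataFrame(
            rows, columns=["depth_rel", "length_rel", "strategy", "predicted_cot"]
        )


def evaluate_surfaces(
    params: CostFunctionParams | None = None,
    depths=DEPTH_GRID,
    lengths=LENGTH_GRID,
    refine: int = 1,
) -> CostSurface:
    """Evaluate both cost surfaces on the grid, optionally refined by an
    integer factor (a refine-times denser grid spanning the same range)."""
    p = params or CostFunctionParams()
    depths = np.asarray(depths, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if refine > 1:
        depths = np.linspace(depths.min(), depths.max(), (len(depths) - 1) * refine + 1)
        lengths = np.linspace(
            lengths.min(), lengths.max(), (len(lengths) - 1) * refine + 1
        )
    over = np.broadcast_to(predict_over_cost(lengths, p), (len(depths), len(lengths)))
    in_ = np.broadcast_to(
        predict_in_cost(depths, p)[:, None], (len(depths), len(lengths))
    )
    return CostSurface(depths, lengths, np.array(over), np.array(in_), p)


def strategy_boundary(surface: CostSurface):
    """Zero-level set of (cost_OVER - cost_IN) by bilinear interpolation.

    Scans each grid row (fixed depth) for sign changes of the cost
    difference along length, seeds each crossing with the linear-interpolant
    zero and refines it against the continuous cost functions (the OVER
    penalty is convex, so the interpolated point alone is only first-order
    accurate).  Returns an (n, 2) array of (depth_rel, length_rel) boundary
    points, empty if the surfaces never intersect on the grid.
    """
    from scipy.optimize import brentq

    p = surface.params
    diff = surface.over - surface.in_
    points: list[tuple[float, float]] = []
    for i, d in enumerate(surface.depths):
        row = diff[i]
        target = predict_in_cost(float(d), p)
        for j in range(len(row) - 1):
            a, b = row[j], row[j + 1]
            if a == 0.0:
                points.append((float(d), float(surface.lengths[j])))
            elif a * b < 0:
                lcross = brentq(
                    lambda ln: predict_over_cost(ln, p) - target,
                    surface.lengths[j],
                    surface.lengths[j + 1],
                    xtol=1e-13,
                )
                points.append((float(d), float(lcross)))
        if row[-1] == 0.0:
            points.append((float(d), float(surface.lengths[-1])))
    return np.array(points).reshape(-1, 2)
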