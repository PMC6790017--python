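"""Calibration of group-mean bony-arch-index (BAI) trajectories.

The group-level decline of the weight-bearing BAI over loading cycles is
modelled as a cubic ``B(c) = b0 + b1 c + b2 c^2 + b3 c^3``.  A cubic is the
lowest-order polynomial with an inflection point, which is how the stage
II -> III transition of creep-like fatigue behaviour is located (the root of
``B''``).  The calibration problem is linear: four independent constraints on
``B`` or its derivatives determine the cubic uniquely.

Because cycle indices span 1..10,000, the Vandermonde system is solved on a
scaled abscissa ``x = c / cycle_scale`` and the coefficients are mapped back
to the raw cycle scale afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CubicConstraint",
    "SingularConstraintsError",
    "NonMonotoneTrajectoryError",
    "calibrate_cubic",
    "calibrate_group_trajectory",
    "evaluate_cubic",
    "cubic_inflection",
]


@dataclass(frozen=True)
class CubicConstraint:
    """A linear constraint on the trajectory cubic.

    order
        Derivative order the constraint applies to: 0 for a value
        ``B(cycle) = value``, 1 for a slope ``B'(cycle) = value``,
        2 for a curvature ``B''(cycle) = value``.
    cycle
        Cycle index (abscissa) at which the constraint holds.
    value
        Constrained value.
    """

    order: int
    cycle: float
    value: float

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError(f"constraint derivative order must be 0, 1 or 2, got {self.order}")


class SingularConstraintsError(ValueError):
    """Raised when the constraint system does not determine a unique cubic."""

    def __init__(self, message: str, dependent: Sequence[int] = ()) -> None:
        super().__init__(message)
        self.dependent = tuple(dependent)


class NonMonotoneTrajectoryError(ValueError):
    """Raised when the calibrated cubic is not non-increasing on the cycle range."""

    def __init__(self, message: str, worst_cycle: float, worst_slope: float) -> None:
        super().__init__(message)
        self.worst_cycle = worst_cycle
        self.worst_slope = worst_slope


def _constraint_row(order: int, x: float) -> np.ndarray:
    # d^order/dx^order of [1, x, x^2, x^3]
    if order == 0:
        return np.array([1.0, x, x * x, x**3])
    if order == 1:
        return np.array([0.0, 1.0, 2.0 * x, 3.0 * x * x])
    return np.array([0.0, 0.0, 2.0, 6.0 * x])


def _find_dependent_rows(rows: np.ndarray) -> list[int]:
    """Indices of constraint rows linearly dependent on the preceding ones."""
    dependent: list[int] = []
    kept: list[np.ndarray] = []
    for i, row in enumerate(rows):
        trial = np.vstack(kept + [row]) if kept else row[None, :]
        if np.linalg.matrix_rank(trial, tol=1e-10 * max(1.0, np.abs(rows).max())) == len(kept):
            dependent.append(i)
        else:
            kept.append(row)
    return dependent


def evaluate_cubic(coef: np.ndarray, cycles: np.ndarray | float) -> np.ndarray | float:
    """Evaluate ``b0 + b1 c + b2 c^2 + b3 c^3`` (coefficients ascending)."""
    return np.polynomial.polynomial.polyval(cycles, np.asarray(coef, dtype=float))


def cubic_inflection(coef: Sequence[float]) -> float:
    """Inflection cycle ``-b2 / (3 b3)`` of a cubic, ``nan`` when b3 == 0."""
    b2, b3 = float(coef[2]), float(coef[3])
    if b3 == 0.0:
        return float("nan")
    return -b2 / (3.0 * b3)


def _check_monotone(coef: np.ndarray, lo: float, hi: float) -> None:
    # B' is quadratic; its maximum on [lo, hi] is at an endpoint or the vertex.
    b1, b2, b3 = coef[1], coef[2], coef[3]
    candidates = [lo, hi]
    if b3 != 0.0:
        vertex = -2.0 * b2 / (6.0 * b3)
        if lo < vertex < hi:
            candidates.append(vertex)
    slopes = [b1 + 2.0 * b2 * c + 3.0 * b3 * c * c for c in candidates]
    worst = int(np.argmax(slopes))
    scale = max(abs(float(s)) for s in slopes) or 1.0
    if slopes[worst] > 1e-9 * scale and slopes[worst] > 0.0:
        raise NonMonotoneTrajectoryError(
            "calibrated cubic is increasing within the cycle range: "
            f"B'({candidates[worst]:.1f}) = {slopes[worst]:.3e} > 0; "
            "the constraints are incompatible with a monotone decline",
            worst_cycle=float(candidates[worst]),
            worst_slope=float(slopes[worst]),
        )


def calibrate_cubic(
    constraints: Iterable[CubicConstraint],
    *,
    cycle_scale: float = 1e4,
    monotone_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Solve for the unique cubic satisfying four linear constraints.

    Parameters
    ----------
    constraints
        Exactly four :class:`CubicConstraint` items.
    cycle_scale
        Internal abscissa scaling (cycles are divided by this before solving,
        coefficients are returned on the raw cycle scale).
    monotone_range
        If given, ``(lo, hi)`` cycle range on which the solution must be
        non-increasing; a violation raises :class:`NonMonotoneTrajectoryError`.

    Returns
    -------
    numpy.ndarray
        Coefficients ``[b0, b1, b2, b3]`` in ascending powers of the cycle.
    """
    cons = list(constraints)
    if len(cons) != 4:
        raise ValueError(f"a cubic needs exactly 4 independent constraints, got {len(cons)}")
    rows = np.vstack([_constraint_row(c.order, c.cycle / cycle_scale) for c in cons])
    rhs = np.array([c.value * cycle_scale ** c.order for c in cons])
    if np.linalg.matrix_rank(rows, tol=1e-10 * max(1.0, np.abs(rows).max())) < 4:
        dep = _find_dependent_rows(rows)
        desc = ", ".join(
            f"#{i} (order-{cons[i].order} at cycle {cons[i].cycle:g})" for i in dep
        )
        raise SingularConstraintsError(
            f"constraint system is singular; linearly dependent constraints: {desc}",
            dependent=dep,
        )
    a = np.linalg.solve(rows, rhs)  # coefficients in scaled x
    coef = a / cycle_scale ** np.arange(4)
    if monotone_range is not None:
        _check_monotone(coef, *monotone_range)
    return coef


def calibrate_group_trajectory(
    anchors: Iterable[tuple[float, float]],
    inflection_cycle: float | None,
    endpoint_bai: float | None,
    *,
    total_cycles: int = 10_000,
    monotone: bool = True,
) -> np.ndarray:
    """Calibrate a group-mean BAI cubic from printed anchors.

    ``anchors`` are ``(cycle, BAI)`` value constraints (e.g. the first-cycle
    BAI and a checkpoint mean read off the study's abstract).  An optional
    curvature constraint ``B''(inflection_cycle) = 0`` pins the creep-stage
    transition, and ``endpoint_bai`` constrains ``B(total_cycles)``.  The
    combined constraint count must be exactly four.
    """
    cons = [CubicConstraint(0, c, v) for c, v in anchors]
    if inflection_cycle is not None:
        cons.append(CubicConstraint(2, float(inflection_cycle), 0.0))
    if endpoint_bai is not None:
        cons.append(CubicConstraint(0, float(total_cycles), float(endpoint_bai)))
    rng = (1.0, float(total_cycles)) if monotone else None
    return calibrate_cubic(cons, cycle_scale=float(total_cycles), monotone_range=rng)
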