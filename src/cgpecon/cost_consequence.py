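"""Cost-consequence ratios, net monetary benefit and deterministic DSA.

Incremental cost-consequence ratios (ICCRs) express the additional
diagnostic cost required to obtain one additional outcome unit (a
patient with an actionable target, an MTB recommendation, or a matched
treatment).  The default comparator is the zero-comparator: no further
diagnostics, zero diagnostic cost, zero diagnostic outcomes.

Net monetary benefit (NMB) monetises the matched-treatment outcome at a
conceptual willingness-to-pay (WTP) threshold per matched treatment:
``NMB = WTP x P(matched) - mean diagnostic cost`` per patient.  Break-even
solvers invert the NMB in the MTB-recommendation uptake and in the CGP
unit cost; one-way and two-way deterministic sensitivity analyses sweep
parameter grids.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .decision_tree import CohortOutcome, evaluate_tree
from .pathway_estimation import (
    CostModel,
    PathwayProbabilities,
    per_patient_diagnostic_cost,
)

#: solver tolerance on re-substituted break-even residuals, EUR
RESIDUAL_TOL = 1e-6


@dataclass(frozen=True)
class IccrSet:
    """Incremental cost per additional outcome unit, per outcome."""

    cost_per_actionable: float | None
    cost_per_mtb_rec: float | None
    cost_per_matched: float | None
    comparator_label: str

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(name for name in
                     ("cost_per_actionable", "cost_per_mtb_rec", "cost_per_matched")
                     if getattr(self, name) is None)


@dataclass(frozen=True)
class NmbResult:
    wtp: float
    n: int
    nmb_per_patient: float
    nmb_total: float


@dataclass(frozen=True)
class BreakEven:
    """A parameter value at which the per-patient NMB crosses zero."""

    parameter_name: str
    value: float
    residual_nmb: float
    flag: str | None = None  # "unattainable" (>1 uptake) or "infeasible" (clamped at 0)


def compute_iccr(outcome: CohortOutcome,
                 comparator: CohortOutcome | None = None) -> IccrSet:
    """ICCRs of ``outcome`` against ``comparator`` (zero-comparator default).

    Ratios whose incremental effect is not positive are flagged undefined
    (dominance or indeterminate); the others are still returned.
    """
    if comparator is None:
        label = "no further diagnostics (zero comparator)"
        delta_cost = outcome.total_cost
        deltas = {
            "cost_per_actionable": outcome.expected_actionable,
            "cost_per_mtb_rec": outcome.expected_mtb_rec,
            "cost_per_matched": outcome.expected_matched,
        }
    else:
        label = "supplied comparator"
        delta_cost = outcome.total_cost - comparator.total_cost
        deltas = {
            "cost_per_actionable":
                outcome.expected_actionable - comparator.expected_actionable,
            "cost_per_mtb_rec":
                outcome.expected_mtb_rec - comparator.expected_mtb_rec,
            "cost_per_matched":
                outcome.expected_matched - comparator.expected_matched,
        }
    ratios = {name: (delta_cost / d if d > 0 else None)
              for name, d in deltas.items()}
    return IccrSet(comparator_label=label, **ratios)


def compute_nmb(outcome: CohortOutcome, wtp: float) -> NmbResult:
    """Per-patient and total NMB at WTP euros per matched treatment."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    p_matched = outcome.expected_matched / outcome.n
    per_patient = wtp * p_matched - outcome.mean_cost
    return NmbResult(wtp=wtp, n=outcome.n, nmb_per_patient=per_patient,
                     nmb_total=outcome.n * per_patient)


def _nmb_from_parameters(probs: PathwayProbabilities, cm: CostModel,
                         wtp: float) -> float:
    return wtp * probs.p_matched_marginal - per_patient_diagnostic_cost(cm, probs)


def break_even_uptake(probs: PathwayProbabilities, cm: CostModel,
                      wtp: float) -> BreakEven:
    """MTB-recommendation uptake at which the per-patient NMB is zero.

    Solves ``wtp x P(MTB rec) x u = mean cost`` for the uptake ``u``; a
    solution above 1 is flagged unattainable.
    """
    p_rec = probs.p_rec_marginal
    if wtp * p_rec <= 0:
        raise ValueError("wtp x P(MTB rec) must be positive to solve for uptake")
    mean_cost = per_patient_diagnostic_cost(cm, probs)
    u = mean_cost / (wtp * p_rec)
    residual = wtp * p_rec * u - mean_cost
    flag = "unattainable" if u > 1.0 else None
    assert abs(residual) < RESIDUAL_TOL
    return BreakEven("p_matched_given_rec", u, residual, flag)


def break_even_cgp_cost(probs: PathwayProbabilities, cm: CostModel,
                        wtp: float) -> BreakEven:
    """CGP unit cost at which the per-patient NMB is zero.

    Solves ``wtp x P(matched) = c x repeat_multiplier + MTB component``
    for ``c``; clamped at 0 with an infeasible flag when the MTB cost
    alone already exceeds the monetised benefit.
    """
    if cm.repeat_multiplier <= 0:
        raise ValueError("repeat_multiplier must be positive")
    benefit = wtp * probs.p_matched_marginal
    mtb_component = (cm.mtb_unit_cost if cm.mtb_per_patient
                     else cm.mtb_unit_cost * probs.p_rec_marginal)
    c = (benefit - mtb_component) / cm.repeat_multiplier
    if c < 0:
        return BreakEven("cgp_unit_cost", 0.0,
                         residual_nmb=benefit - mtb_component,
                         flag="infeasible")
    residual = benefit - (c * cm.repeat_multiplier + mtb_component)
    assert abs(residual) < RESIDUAL_TOL
    return BreakEven("cgp_unit_cost", c, residual, None)


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis
# ---------------------------------------------------------------------------

_DSA_PARAMETERS = ("cgp_unit_cost", "mtb_unit_cost", "uptake", "p_rec",
                   "p_actionable_given_success", "wtp")


def _apply_parameter(name: str, value: float, probs: PathwayProbabilities,
                     cm: CostModel, wtp: float,
                     ) -> tuple[PathwayProbabilities, CostModel, float]:
    if name == "cgp_unit_cost":
        return probs, replace(cm, cgp_unit_cost=value), wtp
    if name == "mtb_unit_cost":
        return probs, replace(cm, mtb_unit_cost=value), wtp
    if name == "uptake":
        return replace(probs, p_matched_given_rec=value), cm, wtp
    if name == "p_rec":
        return replace(probs, p_rec_given_actionable=value), cm, wtp
    if name == "p_actionable_given_success":
        return replace(probs, p_actionable_given_success=value), cm, wtp
    if name == "wtp":
        return probs, cm, value
    raise ValueError(
        f"unknown parameter {name!r}; expected one of {_DSA_PARAMETERS}")


def one_way_dsa(parameter_name: str, grid: Sequence[float],
                probs: PathwayProbabilities, cm: CostModel,
                wtp: float) -> list[tuple[float, float]]:
    """Per-patient NMB along a one-parameter grid, all else held fixed."""
    curve = []
    for value in grid:
        p, c, w = _apply_parameter(parameter_name, value, probs, cm, wtp)
        curve.append((float(value), _nmb_from_parameters(p, c, w)))
    return curve


def two_way_dsa(cost_grid: Sequence[float], uptake_grid: Sequence[float],
                probs: PathwayProbabilities, cm: CostModel, wtp: float,
                ) -> tuple[np.ndarray, list[tuple[float, float | None]]]:
    """NMB surface over (CGP cost, uptake) and the zero-NMB frontier.

    The frontier gives, for each CGP cost, the smallest uptake with
    NMB >= 0, linearly interpolated between grid points; ``None`` when no
    uptake on the grid achieves a nonnegative NMB.
    """
    if len(cost_grid) == 0 or len(uptake_grid) == 0:
        raise ValueError("cost_grid and uptake_grid must be nonempty")
    surface = np.empty((len(cost_grid), len(uptake_grid)))
    for i, cost in enumerate(cost_grid):
        for j, uptake in enumerate(uptake_grid):
            p, c, w = _apply_parameter("uptake", uptake, probs,
                                       replace(cm, cgp_unit_cost=cost), wtp)
            surface[i, j] = _nmb_from_parameters(p, c, w)
    frontier: list[tuple[float, float | None]] = []
    for i, cost in enumerate(cost_grid):
        row = surface[i]
        crossing: float | None = None
        if row[0] >= 0:
            crossing = float(uptake_grid[0])
        else:
            for j in range(1, len(uptake_grid)):
                if row[j] >= 0:
                    u0, u1 = uptake_grid[j - 1], uptake_grid[j]
                    y0, y1 = row[j - 1], row[j]
                    crossing = float(u0 + (0.0 - y0) * (u1 - u0) / (y1 - y0))
                    break
        frontier.append((float(cost), crossing))
    return surface, frontier


def basecase_outcome(probs: PathwayProbabilities, cm: CostModel,
                     n: int) -> CohortOutcome:
    """Convenience: the base-case tree evaluation used by reports."""
    return evaluate_tree(probs, cm, n)
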