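"""Discounted cost/QALY accrual, incremental cost-utility ratios, and the
dominance frontier.

Conventions: screening costs fall at t=0 undiscounted; utilities and annual
program costs accrue at the end of each cycle t = 1..horizon and are
discounted by 1/(1+r)^t (no half-cycle correction).  The incremental
cost-utility ratio between strategies a and b is
(cost_a - cost_b) / (qaly_a - qaly_b), in USD per QALY.  The strategy chosen
at a willingness-to-pay (WTP) threshold is the highest-QALY non-dominated
strategy whose frontier ICUR does not exceed the threshold; this coincides
with maximizing net monetary benefit NMB = WTP * QALY - cost, and both
routes are computed and cross-asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .cascade import CascadeResult, CohortSlice
    from .markov import Trajectory
    from .params import ParameterSet

__all__ = [
    "EconResult",
    "Icur",
    "FrontierDecision",
    "discount_factor",
    "discount_weights",
    "accrue",
    "icur",
    "nmb",
    "frontier",
    "UndefinedIcurError",
]


class UndefinedIcurError(ZeroDivisionError):
    """Equal QALYs make the cost-utility ratio undefined."""


def discount_factor(rate: float, t: int) -> float:
    """Present-value factor 1/(1+rate)^t for an end-of-cycle-t accrual."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if t < 0 or int(t) != t:
        raise ValueError("cycle index must be a nonnegative integer")
    return (1.0 + rate) ** -int(t)


def discount_weights(rate: float, horizon: int) -> np.ndarray:
    """Vector of factors for cycles 1..horizon."""
    return (1.0 + rate) ** -np.arange(1, horizon + 1, dtype=float)


@dataclass(frozen=True)
class EconResult:
    """Discounted totals for one strategy, absolute and versus the reference."""

    strategy_id: str
    total_cost: float
    total_qaly: float
    incremental_cost: float | None = None
    incremental_qaly: float | None = None

    def with_reference(self, ref: "EconResult") -> "EconResult":
        return replace(self,
                       incremental_cost=self.total_cost - ref.total_cost,
                       incremental_qaly=self.total_qaly - ref.total_qaly)


def accrue(pairs: Sequence[tuple["CohortSlice", "Trajectory"]],
           one_off_cost_per_child: float,
           params: "ParameterSet",
           strategy_id: str = "") -> EconResult:
    """Accrue discounted costs and QALYs over a full cohort of slices.

    ``pairs`` couples each cohort slice (carrying its cohort fraction and
    program membership) with its state trajectory.  All trajectories must
    share one horizon.  Totals are scaled to ``params.cohort_size`` children.
    """
    H = params.horizon_years
    for _, traj in pairs:
        if traj.horizon != H:
            raise ValueError(
                f"trajectory horizon {traj.horizon} != configured horizon {H}")
    u = params.utilities.point_vector()
    disc = discount_weights(params.discount_rate, H)
    program_annuity = disc[:params.program_duration].sum()
    size = params.cohort_size

    total_qaly = 0.0
    program_fraction = 0.0
    for sl, traj in pairs:
        per_cycle_utility = traj.states[1:] @ u  # cycles 1..H
        total_qaly += sl.fraction * float(per_cycle_utility @ disc)
        if sl.program:
            program_fraction += sl.fraction
    total_qaly *= size
    total_cost = size * (one_off_cost_per_child
                         + program_fraction * params.costs.program_annual
                         * program_annuity)
    return EconResult(strategy_id=strategy_id, total_cost=total_cost,
                      total_qaly=total_qaly)


@dataclass(frozen=True)
class Icur:
    """A pairwise incremental cost-utility ratio with quadrant flag.

    ``label`` is ``"icur"`` for an informative ratio, ``"dominant"`` when the
    first strategy is cheaper and more effective (ratio misleading),
    ``"dominated"`` when costlier and less effective, and ``"undefined"``
    when the QALY difference is zero.
    """

    value: float  # NaN when undefined
    label: str
    delta_cost: float
    delta_qaly: float

    def __float__(self) -> float:
        return self.value


def icur(a: EconResult, b: EconResult) -> Icur:
    """ICUR of strategy ``a`` versus ``b``: (cost_a - cost_b)/(qaly_a - qaly_b)."""
    dc = a.total_cost - b.total_cost
    dq = a.total_qaly - b.total_qaly
    if dq == 0.0:
        return Icur(math.nan, "undefined", dc, dq)
    value = dc / dq
    if dc <= 0.0 and dq > 0.0:
        label = "dominant"
    elif dc >= 0.0 and dq < 0.0:
        label = "dominated"
    else:
        label = "icur"
    return Icur(value, label, dc, dq)


def nmb(result: EconResult, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    return wtp * result.total_qaly - result.total_cost


@dataclass(frozen=True)
class FrontierDecision:
    """Dominance analysis of a strategy set at one WTP threshold."""

    wtp: float
    ordering: tuple[str, ...]            # all strategies by ascending cost
    strictly_dominated: frozenset[str]
    extended_dominated: frozenset[str]
    frontier: tuple[str, ...]            # non-dominated, ascending cost
    frontier_icurs: dict[str, float]     # vs the previous frontier member
    optimal: str

    @property
    def dominated(self) -> frozenset[str]:
        return self.strictly_dominated | self.extended_dominated


def frontier(results: Iterable[EconResult], wtp: float) -> FrontierDecision:
    """Efficiency-frontier decision at one WTP threshold.

    Strictly dominated strategies (costlier, no more QALYs) are removed
    first; extendedly dominated ones (a costlier alternative has a lower
    pairwise ICUR) next.  The optimal strategy is the last frontier member
    whose incremental ICUR is <= wtp, verified against the net-monetary-
    benefit maximizer.
    """
    res = sorted(results, key=lambda r: (r.total_cost, r.total_qaly))
    if len(res) < 2:
        raise ValueError("frontier needs at least 2 strategies")
    ordering = tuple(r.strategy_id for r in res)

    strictly = set()
    for r in res:
        for other in res:
            if other is r:
                continue
            if (other.total_cost <= r.total_cost
                    and other.total_qaly >= r.total_qaly
                    and (other.total_cost < r.total_cost
                         or other.total_qaly > r.total_qaly)):
                strictly.add(r.strategy_id)
                break

    frontier_res = [r for r in res if r.strategy_id not in strictly]
    extended = set()
    changed = True
    while changed and len(frontier_res) > 2:
        changed = False
        ratios = [icur(frontier_res[i], frontier_res[i - 1]).value
                  for i in range(1, len(frontier_res))]
        for i in range(len(ratios) - 1):
            if ratios[i] > ratios[i + 1]:  # middle strategy off the frontier
                extended.add(frontier_res[i + 1].strategy_id)
                del frontier_res[i + 1]
                changed = True
                break

    icurs: dict[str, float] = {}
    optimal = frontier_res[0]
    for prev, cur in zip(frontier_res, frontier_res[1:]):
        ratio = icur(cur, prev).value
        icurs[cur.strategy_id] = ratio
        if ratio <= wtp:
            optimal = cur

    # cross-check against net monetary benefit (ties -> higher QALY);
    # tolerance guards pure float cancellation, not genuine disagreement
    best_nmb = max(frontier_res, key=lambda r: (nmb(r, wtp), r.total_qaly))
    gap = nmb(best_nmb, wtp) - nmb(optimal, wtp)
    if (best_nmb.strategy_id != optimal.strategy_id
            and gap > 1e-9 * max(1.0, abs(nmb(best_nmb, wtp)))):  # pragma: no cover
        raise AssertionError(
            f"frontier rule ({optimal.strategy_id}) and NMB maximization "
            f"({best_nmb.strategy_id}) disagree at wtp={wtp}")

    return FrontierDecision(
        wtp=wtp, ordering=ordering,
        strictly_dominated=frozenset(strictly),
        extended_dominated=frozenset(extended),
        frontier=tuple(r.strategy_id for r in frontier_res),
        frontier_icurs=icurs,
        optimal=optimal.strategy_id)
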