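"""End-to-end evaluation: cohort -> decision tree -> Markov -> economics.

`evaluate_strategy` runs one screening strategy over the full (age, sex)
stratified cohort and returns its discounted economic totals;
`run_base_case` evaluates all four strategies on the identical cohort,
fills incremental results against the no-screening reference (S4), and
resolves the frontier decision at each configured willingness-to-pay
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cascade import (STRATEGIES, CohortSlice, StrategySpec, assign_management,
                      run_cascade)
from .cohort import CohortSpec, generate_cohort
from .economics import EconResult, FrontierDecision, accrue, frontier, icur
from .markov import ScenarioFlags, Trajectory, build_transition_matrix, run_horizon
from .params import ParameterSet, default_parameters

__all__ = ["evaluate_strategy", "run_base_case", "BaseCaseResult",
           "results_table", "REFERENCE_STRATEGY"]

REFERENCE_STRATEGY = "S4"


def _cohort_spec(params: ParameterSet,
                 spec: CohortSpec | None) -> CohortSpec:
    if spec is not None:
        return spec
    ages = tuple(sorted(params.prevalence_by_age))
    return CohortSpec(size=params.cohort_size, ages=ages)


class _TrajectoryCache:
    """Shares trajectories between slices with identical disease dynamics.

    Dynamics depend only on (sex, regime, baseline age); baseline age
    matters only when the adolescent scenario flag is active.
    """

    def __init__(self, params: ParameterSet, flags: ScenarioFlags):
        self.params = params
        self.flags = flags
        self._traj: dict[tuple, np.ndarray] = {}
        self._matrices: dict[tuple, np.ndarray] = {}

    def _provider(self, sex: str, regime: str, age: int) -> np.ndarray:
        age_key = age if (self.flags.adolescent_transitions
                          and age >= self.flags.adolescent_age) else None
        key = (sex, regime, age_key)
        m = self._matrices.get(key)
        if m is None:
            m = build_transition_matrix(sex, regime, age,
                                        self.params.transitions, self.flags)
            self._matrices[key] = m
        return m

    def trajectory(self, sl: CohortSlice) -> Trajectory:
        if not sl.diseased:
            key = ("healthy",)
        else:
            age_key = (sl.age if self.flags.adolescent_transitions else None)
            key = (sl.sex, sl.regime, age_key)
        states = self._traj.get(key)
        if states is None:
            traj = run_horizon(sl, self.params, self.flags,
                               matrix_provider=self._provider)
            states = traj.states
            self._traj[key] = states
        return Trajectory(states=states, arm=sl.arm, sex=sl.sex, age=sl.age,
                          fraction=sl.fraction)


def evaluate_strategy(strategy: str | StrategySpec, params: ParameterSet,
                      flags: ScenarioFlags = ScenarioFlags(),
                      cohort_spec: CohortSpec | None = None) -> EconResult:
    """Discounted cost and QALY totals for one strategy over the cohort."""
    spec = strategy if isinstance(strategy, StrategySpec) else STRATEGIES[strategy]
    cspec = _cohort_spec(params, cohort_spec)
    strata = generate_cohort(cspec)
    cache = _TrajectoryCache(params, flags)
    rho = params.transitions.response_rate

    pairs: list[tuple[CohortSlice, Trajectory]] = []
    one_off = 0.0
    for stratum in strata:
        weight = stratum.weight(cspec.size)
        cas = run_cascade(spec, params, stratum.age)
        one_off += weight * cas.one_off_cost_per_child
        for sl in assign_management(cas, rho, params.initial_stage_distribution,
                                    sex=stratum.sex):
            scaled = replace(sl, fraction=sl.fraction * weight)
            pairs.append((scaled, cache.trajectory(scaled)))
    return accrue(pairs, one_off, params, strategy_id=spec.id)


@dataclass
class BaseCaseResult:
    """All four strategies on one cohort, plus frontier decisions."""

    results: dict[str, EconResult]
    decisions: dict[float, FrontierDecision]
    params: ParameterSet

    def optimal(self, wtp: float) -> str:
        return self.decisions[wtp].optimal

    def icur_vs_reference(self, strategy_id: str) -> float:
        return icur(self.results[strategy_id],
                    self.results[REFERENCE_STRATEGY]).value


def run_base_case(params: ParameterSet | None = None,
                  flags: ScenarioFlags = ScenarioFlags(),
                  cohort_spec: CohortSpec | None = None) -> BaseCaseResult:
    """Evaluate S1-S4 on the identical cohort and resolve WTP decisions."""
    if params is None:
        params = default_parameters()
    results = {sid: evaluate_strategy(sid, params, flags, cohort_spec)
               for sid in STRATEGIES}
    ref = results[REFERENCE_STRATEGY]
    results = {sid: r.with_reference(ref) for sid, r in results.items()}
    decisions = {wtp: frontier(results.values(), wtp)
                 for wtp in params.wtp_thresholds}
    return BaseCaseResult(results=results, decisions=decisions, params=params)


def results_table(base: BaseCaseResult) -> pd.DataFrame:
    """Strategy summary in the conventional reporting shape.

    Costs and QALYs are incremental versus the no-screening reference
    (which therefore reads 0 / 0 / Reference), costs additionally in
    million USD.
    """
    rows = []
    for sid, r in sorted(base.results.items()):
        ratio = base.icur_vs_reference(sid)
        rows.append({
            "strategy": sid,
            "cost_usd": r.incremental_cost,
            "cost_million_usd": round(r.incremental_cost / 1e6, 2),
            "qaly": round(r.incremental_qaly, 1),
            "icur_vs_reference":
                "Reference" if sid == REFERENCE_STRATEGY else round(ratio, 1),
            "total_cost_usd": r.total_cost,
            "total_qaly": r.total_qaly,
        })
    return pd.DataFrame(rows)
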