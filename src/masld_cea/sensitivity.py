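"""Sensitivity analyses: one-way (tornado), scenarios, two-way dominance
maps, and probabilistic sensitivity analysis (PSA) with cost-effectiveness
acceptability curves (CEACs).

PSA draws every Beta-distributed input independently per iteration (costs
and probabilities without printed intervals stay fixed; no parameter
correlations), runs all four strategies on the common draw, and records the
economic results.  CEACs report, over a WTP grid, (a) the fraction of
iterations where each screening strategy has higher net monetary benefit
than no screening, and (b) the fraction where it maximizes net monetary
benefit (ties broken toward lower cost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cascade import STRATEGY_IDS
from .economics import icur
from .markov import ScenarioFlags
from .params import (ConfigError, ParameterSet, UncertainValue,
                     default_parameters, with_override)
from .pipeline import REFERENCE_STRATEGY, BaseCaseResult, run_base_case

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "PSAResult",
    "CEACCurve",
    "one_way",
    "tornado",
    "default_one_way_ranges",
    "standard_scenarios",
    "run_scenarios",
    "two_way",
    "draw_parameters",
    "run_psa",
    "ceac",
    "DEFAULT_WTP_GRID",
]

DEFAULT_WTP_GRID = tuple(float(w) for w in range(0, 100_001, 1000))
_PAIRS = (("S1", "S4"), ("S2", "S4"), ("S3", "S4"), ("S2", "S1"), ("S3", "S2"))


# ---------------------------------------------------------------------------
# one-way / tornado

def default_one_way_ranges(params: ParameterSet) -> dict[str, tuple[float, float]]:
    """Low/high bounds per parameter: printed 95% CI endpoints where
    available, otherwise +/-20% around the point estimate (probabilities
    clipped to [0, 1])."""
    ranges: dict[str, tuple[float, float]] = {}
    for name, uv in params.iter_uncertain():
        if not uv.is_fixed:
            ranges[name] = (uv.ci_low, uv.ci_high)
    pm20 = {
        "whtr_positivity": params.whtr_positivity,
        "transitions.regression": params.transitions.regression,
        "transitions.treated_regression": params.transitions.treated_regression,
        "transitions.response_rate": params.transitions.response_rate,
        "costs.routine_exam": params.costs.routine_exam,
        "costs.ultrasound": params.costs.ultrasound,
        "costs.fibroscan": params.costs.fibroscan,
        "costs.mri_pdff": params.costs.mri_pdff,
        "costs.blood_panel": params.costs.blood_panel,
        "costs.program_fixed_annual": params.costs.program_fixed_annual,
        "costs.program_variable_annual": params.costs.program_variable_annual,
    }
    for name, v in pm20.items():
        lo, hi = 0.8 * v, 1.2 * v
        if not name.startswith("costs."):
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        ranges[name] = (lo, hi)
    return ranges


def _pairwise_icurs(base: BaseCaseResult) -> dict[str, float]:
    return {f"icur_{a}_vs_{b}".lower():
            icur(base.results[a], base.results[b]).value
            for a, b in _PAIRS}


def one_way(param: str, low: float, high: float, params: ParameterSet,
            wtp_list: Sequence[float] | None = None) -> pd.DataFrame:
    """Re-run the full pipeline at each bound of one parameter.

    Returns one row per bound with every pairwise ICUR and, per WTP
    threshold, the frontier-optimal strategy.  Bounds that violate a
    structural invariant are skipped with a logged warning.
    """
    wtps = tuple(wtp_list) if wtp_list is not None else params.wtp_thresholds
    rows = []
    for bound_name, bound in (("low", low), ("high", high)):
        try:
            ps = with_override(params, param, bound)
            base = run_base_case(ps)
        except (ConfigError, ValueError) as exc:
            logger.warning("one-way bound skipped: %s=%s (%s)", param, bound, exc)
            continue
        row = {"parameter": param, "bound": bound_name, "value": bound}
        row.update(_pairwise_icurs(base))
        for wtp in wtps:
            row[f"optimal_at_{wtp:.0f}"] = base.decisions[wtp].optimal
        rows.append(row)
    return pd.DataFrame(rows)


def tornado(params: ParameterSet | None = None,
            ranges: Mapping[str, tuple[float, float]] | None = None,
            comparison: str = "icur_s2_vs_s4") -> pd.DataFrame:
    """One-way analysis over every model parameter, sorted by ICUR swing."""
    if params is None:
        params = default_parameters()
    if ranges is None:
        ranges = default_one_way_ranges(params)
    frames = [one_way(name, lo, hi, params) for name, (lo, hi) in ranges.items()]
    table = pd.concat([f for f in frames if not f.empty], ignore_index=True)
    swing = (table.groupby("parameter")[comparison]
             .agg(lambda s: float(s.max() - s.min()))
             .rename("swing"))
    table = table.merge(swing, on="parameter")
    return table.sort_values(["swing", "parameter", "bound"],
                             ascending=[False, True, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# scenarios

@dataclass(frozen=True)
class ScenarioConfig:
    """A named deviation from the base case."""

    name: str
    discount_rate: float | None = None
    response_rate: float | None = None
    horizon_years: int | None = None
    reduced_advanced_response: bool = False
    adolescent_transitions: bool = False

    def __post_init__(self) -> None:
        if self.response_rate is not None and not (0.30 <= self.response_rate <= 1.00):
            raise ValueError("response_rate override must be in [0.30, 1.00]")
        if self.horizon_years is not None and self.horizon_years not in (1, 5, 10):
            raise ValueError("horizon override must be 1, 5 or 10")

    def apply(self, params: ParameterSet) -> tuple[ParameterSet, ScenarioFlags]:
        ps = params
        if self.discount_rate is not None:
            ps = with_override(ps, "discount_rate", self.discount_rate)
        if self.response_rate is not None:
            ps = with_override(ps, "transitions.response_rate", self.response_rate)
        if self.horizon_years is not None:
            ps = with_override(ps, "horizon_years", self.horizon_years)
        flags = ScenarioFlags(
            reduced_advanced_response=self.reduced_advanced_response,
            adolescent_transitions=self.adolescent_transitions)
        return ps, flags


def standard_scenarios() -> list[ScenarioConfig]:
    """The scenario suite run alongside the base case."""
    return [
        ScenarioConfig("discount_0pct", discount_rate=0.0),
        ScenarioConfig("discount_5pct", discount_rate=0.05),
        ScenarioConfig("response_30pct", response_rate=0.30),
        ScenarioConfig("response_100pct", response_rate=1.00),
        ScenarioConfig("reduced_advanced_response",
                       reduced_advanced_response=True),
        ScenarioConfig("adolescent_transitions", adolescent_transitions=True),
        ScenarioConfig("horizon_1y", horizon_years=1),
        ScenarioConfig("horizon_5y", horizon_years=5),
    ]


def run_scenarios(scenarios: Iterable[ScenarioConfig] | None = None,
                  params: ParameterSet | None = None) -> pd.DataFrame:
    """One full pipeline run per scenario (plus the base case).

    Each row reports per-strategy incremental cost/QALYs, pairwise ICURs,
    the WTP-optimal strategy, and whether each screening strategy is
    cost-effective (ICUR vs reference <= threshold) at each threshold.
    """
    if params is None:
        params = default_parameters()
    if scenarios is None:
        scenarios = standard_scenarios()
    rows = []
    for sc in [ScenarioConfig("base_case"), *scenarios]:
        ps, flags = sc.apply(params)
        base = run_base_case(ps, flags)
        row: dict = {"scenario": sc.name}
        for sid, r in sorted(base.results.items()):
            row[f"cost_{sid}".lower()] = r.incremental_cost
            row[f"qaly_{sid}".lower()] = r.incremental_qaly
        row.update(_pairwise_icurs(base))
        for wtp in ps.wtp_thresholds:
            row[f"optimal_at_{wtp:.0f}"] = base.decisions[wtp].optimal
            for sid in ("S1", "S2", "S3"):
                ratio = base.icur_vs_reference(sid)
                row[f"ce_{sid}_at_{wtp:.0f}".lower()] = bool(ratio <= wtp)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-way

def two_way(test_name: str, se_grid: Sequence[float], sp_grid: Sequence[float],
            params: ParameterSet | None = None,
            wtp: float | None = None) -> pd.DataFrame:
    """Dominance map over a sensitivity/specificity grid of one test.

    Only the named test's performance is overridden per cell; comparators
    stay at base case.  Long format: one row per (se, sp) cell with the
    WTP-optimal strategy and all pairwise ICURs.
    """
    if params is None:
        params = default_parameters()
    if wtp is None:
        wtp = params.wtp_thresholds[0]
    from .economics import frontier
    rows = []
    for se in se_grid:
        ps_se = with_override(params, f"tests.{test_name}.sensitivity", se)
        for sp in sp_grid:
            ps = with_override(ps_se, f"tests.{test_name}.specificity", sp)
            base = run_base_case(ps)
            row = {"test": test_name, "se": se, "sp": sp,
                   "optimal": frontier(base.results.values(), wtp).optimal}
            row.update(_pairwise_icurs(base))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def _apply_draws(params: ParameterSet, draws: Mapping[str, float]) -> ParameterSet:
    """Fast point-mass substitution of drawn values into a ParameterSet."""
    from dataclasses import replace as dc_replace

    from .params import (SEXES, TEST_NAMES, ProgressionRates, TestPerformance,
                         UtilitySchedule)

    def fx(name: str, current: UncertainValue) -> UncertainValue:
        v = draws.get(name)
        return current if v is None else UncertainValue.fixed(v)

    tests = {name: TestPerformance(
        name,
        fx(f"tests.{name}.sensitivity", params.tests[name].sensitivity),
        fx(f"tests.{name}.specificity", params.tests[name].specificity))
        for name in TEST_NAMES}
    utilities = UtilitySchedule(
        f0=fx("utilities.f0", params.utilities.f0),
        f1_f2=fx("utilities.f1_f2", params.utilities.f1_f2),
        f3=fx("utilities.f3", params.utilities.f3),
        f4=fx("utilities.f4", params.utilities.f4))
    moves = ("f0_to_f1", "f1_to_f2", "f2_to_f3", "f3_to_f4")
    prog = {sex: ProgressionRates(**{
        m: fx(f"transitions.{sex}.{m}", getattr(params.transitions.progression(sex), m))
        for m in moves}) for sex in SEXES}
    transitions = dc_replace(params.transitions, boys=prog["boys"],
                             girls=prog["girls"])
    ps = dc_replace(params, tests=tests, utilities=utilities,
                    transitions=transitions)
    ps.transitions.validate_rows()  # structural check; ordering not enforced
    return ps


def draw_parameters(params: ParameterSet, rng: np.random.Generator,
                    max_redraws: int = 100) -> tuple[ParameterSet, dict[str, float], int]:
    """One joint PSA draw: every Beta-kind input sampled independently.

    F1/F2 utilities are a single shared input, so one draw covers both.
    Structurally invalid draws (progression + regression > 1 in any state)
    are rejected and redrawn; the redraw count is returned.
    """
    redraws = 0
    while True:
        draws = {name: float(uv.sample(rng))
                 for name, uv in params.iter_uncertain() if not uv.is_fixed}
        try:
            return _apply_draws(params, draws), draws, redraws
        except ConfigError:
            redraws += 1
            if redraws > max_redraws:
                raise
            logger.warning("structurally invalid PSA draw rejected (%d)", redraws)


@dataclass
class PSAResult:
    """Monte Carlo parameter draws and per-iteration economic results."""

    draws: pd.DataFrame      # one row per iteration: drawn parameter values
    results: pd.DataFrame    # rows (iteration, strategy, cost, qaly)
    n_iter: int
    seed: int
    redraws: int = 0

    def costs_qalys(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_iter, n_strategies) arrays in STRATEGY_IDS order."""
        wide_c = self.results.pivot(index="iteration", columns="strategy",
                                    values="cost")[list(STRATEGY_IDS)]
        wide_q = self.results.pivot(index="iteration", columns="strategy",
                                    values="qaly")[list(STRATEGY_IDS)]
        return wide_c.to_numpy(), wide_q.to_numpy()


def run_psa(params: ParameterSet | None = None, n_iter: int = 1000,
            seed: int = 0, cohort_size: int | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis with common random draws.

    All four strategies are evaluated on the same parameter draw each
    iteration, so per-iteration frontier comparisons are coherent.  Fully
    reproducible from ``seed``.
    """
    if params is None:
        params = default_parameters()
    if cohort_size is not None:
        params = with_override(params, "cohort_size", cohort_size)
    rng = np.random.default_rng(seed)
    draw_rows, result_rows = [], []
    total_redraws = 0
    for it in range(n_iter):
        ps, draws, redraws = draw_parameters(params, rng)
        total_redraws += redraws
        base = run_base_case(ps)
        draw_rows.append({"iteration": it, **draws})
        for sid, r in base.results.items():
            result_rows.append({"iteration": it, "strategy": sid,
                                "cost": r.total_cost, "qaly": r.total_qaly})
    return PSAResult(draws=pd.DataFrame(draw_rows),
                     results=pd.DataFrame(result_rows),
                     n_iter=n_iter, seed=seed, redraws=total_redraws)


@dataclass
class CEACCurve:
    """Acceptability probabilities over a WTP grid.

    ``vs_reference`` holds P(NMB(strategy) > NMB(no screening));
    ``optimal`` holds P(strategy maximizes NMB), summing to 1 at each WTP.
    """

    wtp: np.ndarray
    vs_reference: pd.DataFrame  # columns per strategy
    optimal: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"wtp": self.wtp})
        for sid in self.vs_reference.columns:
            out[f"p_ce_{sid}_vs_{REFERENCE_STRATEGY}".lower()] = \
                self.vs_reference[sid].to_numpy()
        for sid in self.optimal.columns:
            out[f"p_optimal_{sid}".lower()] = self.optimal[sid].to_numpy()
        return out


def ceac(psa: PSAResult, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> CEACCurve:
    """Cost-effectiveness acceptability curves from PSA iterations.

    The optimal-strategy winner per iteration is the NMB maximizer with
    ties broken toward lower cost.
    """
    if psa.n_iter < 1:
        raise ValueError("PSA result is empty")
    costs, qalys = psa.costs_qalys()          # (n_iter, 4)
    wtps = np.asarray(list(wtp_grid), dtype=float)
    ref = list(STRATEGY_IDS).index(REFERENCE_STRATEGY)

    p_vs_ref = np.empty((len(wtps), len(STRATEGY_IDS)))
    p_opt = np.empty_like(p_vs_ref)
    for i, w in enumerate(wtps):
        nmb_mat = w * qalys - costs           # (n_iter, 4)
        p_vs_ref[i] = (nmb_mat > nmb_mat[:, [ref]]).mean(axis=0)
        # argmax with ties toward lower cost: penalize cost by an epsilon rank
        best = nmb_mat.max(axis=1, keepdims=True)
        is_best = nmb_mat >= best - 1e-9 * np.maximum(1.0, np.abs(best))
        cost_masked = np.where(is_best, costs, np.inf)
        winner = cost_masked.argmin(axis=1)
        p_opt[i] = np.bincount(winner, minlength=len(STRATEGY_IDS)) / psa.n_iter
    return CEACCurve(
        wtp=wtps,
        vs_reference=pd.DataFrame(p_vs_ref, columns=list(STRATEGY_IDS)),
        optimal=pd.DataFrame(p_opt, columns=list(STRATEGY_IDS)))
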