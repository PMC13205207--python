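"""Two-stage screening decision tree.

Stage 1 is the waist-to-height ratio (WHtR >= 0.48), which flags a fixed
fraction of the cohort (22.6% at base case).  Stage 2 applies one imaging
test — ultrasound (S1), FibroScan/CAP (S2), or MRI-PDFF (S3) — to the
WHtR-positives, partitioning the cohort into true/false positives and
negatives plus the WHtR-negative diseased/healthy remainder.  S4 is no
screening.  Second-stage positives enter the lifestyle-modification program;
a configurable response rate determines who follows the intervention
transition regime.

The prevalence among WHtR-positives is derived from the age-specific
population prevalence pi(age), the stage-1 sensitivity sigma1 (fraction of
diseased children captured by the WHtR cut-off; 1.0 at base case), and the
WHtR positivity rho_+:  pi_cond = pi * sigma1 / rho_+.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .params import ConfigError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .params import ParameterSet

__all__ = [
    "StrategySpec",
    "STRATEGIES",
    "STRATEGY_IDS",
    "CascadeResult",
    "CohortSlice",
    "classify_second_stage",
    "run_cascade",
    "assign_management",
]

_FRACTION_TOL = 1e-12


@dataclass(frozen=True)
class StrategySpec:
    """A screening strategy: stage-1 WHtR plus an optional second-stage test."""

    id: str
    second_stage: str | None  # test name, or None for no screening

    @property
    def screens(self) -> bool:
        return self.second_stage is not None


STRATEGIES = {
    "S1": StrategySpec("S1", "ultrasound"),
    "S2": StrategySpec("S2", "fibroscan"),
    "S3": StrategySpec("S3", "mri_pdff"),
    "S4": StrategySpec("S4", None),
}
STRATEGY_IDS = tuple(STRATEGIES)


def classify_second_stage(prevalence_among_tested: float, se: float,
                          sp: float) -> tuple[float, float, float, float]:
    """Split the tested subgroup into (tp, fn, fp, tn) fractions.

    tp = pi*se, fn = pi*(1-se), fp = (1-pi)*(1-sp), tn = (1-pi)*sp.
    """
    for name, v in (("prevalence", prevalence_among_tested), ("se", se), ("sp", sp)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    pi = prevalence_among_tested
    return pi * se, pi * (1.0 - se), (1.0 - pi) * (1.0 - sp), (1.0 - pi) * sp


@dataclass(frozen=True)
class CascadeResult:
    """Decision-tree outcome for one (strategy, age): cohort-fraction arms.

    The six arm fractions partition the cohort; ``tp + fn +
    whtr_neg_diseased`` equals the overall prevalence at that age.
    ``one_off_cost_per_child`` is the t=0 screening cost averaged over every
    child in the cohort.
    """

    strategy_id: str
    age: int
    prevalence: float
    tp: float
    fp: float
    tn: float
    fn: float
    whtr_neg_diseased: float
    whtr_neg_healthy: float
    responder_fraction: float
    one_off_cost_per_child: float

    def arm_fractions(self) -> np.ndarray:
        return np.array([self.tp, self.fp, self.tn, self.fn,
                         self.whtr_neg_diseased, self.whtr_neg_healthy])

    def __post_init__(self) -> None:
        arms = self.arm_fractions()
        if np.any(arms < -_FRACTION_TOL):
            raise ValueError("arm fractions must be >= 0")
        if abs(arms.sum() - 1.0) > 1e-9:
            raise ValueError(f"arm fractions must sum to 1, got {arms.sum()!r}")


def run_cascade(strategy: StrategySpec, params: "ParameterSet",
                age: int) -> CascadeResult:
    """Run the decision tree for one strategy at one baseline age."""
    pi = params.prevalence(age)
    sigma1 = params.whtr_stage1_sensitivity
    if not strategy.screens:
        return CascadeResult(
            strategy_id=strategy.id, age=age, prevalence=pi,
            tp=0.0, fp=0.0, tn=0.0, fn=0.0,
            whtr_neg_diseased=pi, whtr_neg_healthy=1.0 - pi,
            responder_fraction=0.0, one_off_cost_per_child=0.0)

    pos = params.whtr_positivity
    captured = pi * sigma1
    if captured > pos + 1e-12:
        raise ConfigError(
            f"stage-1 sensitivity {sigma1} captures {captured:.4f} of the cohort "
            f"but WHtR positivity is only {pos}: conditional prevalence > 1")
    pi_cond = min(captured / pos, 1.0)

    perf = params.tests[strategy.second_stage]
    tp_c, fn_c, fp_c, tn_c = classify_second_stage(
        pi_cond, perf.sensitivity.mean, perf.specificity.mean)
    tp, fn, fp, tn = (pos * x for x in (tp_c, fn_c, fp_c, tn_c))
    neg_diseased = pi * (1.0 - sigma1)
    neg_healthy = 1.0 - pos - neg_diseased

    cost = params.costs.routine_exam + pos * params.costs.second_stage(
        strategy.second_stage)
    if params.blood_panel_all_whtr_positive:
        cost += pos * params.costs.blood_panel
    else:
        cost += (tp + fp) * params.costs.blood_panel

    return CascadeResult(
        strategy_id=strategy.id, age=age, prevalence=pi,
        tp=tp, fp=fp, tn=tn, fn=fn,
        whtr_neg_diseased=neg_diseased, whtr_neg_healthy=neg_healthy,
        responder_fraction=tp * params.transitions.response_rate,
        one_off_cost_per_child=cost)


@dataclass(frozen=True)
class CohortSlice:
    """A homogeneous post-screening subgroup entering the Markov model."""

    arm: str
    fraction: float          # fraction of the full cohort
    diseased: bool
    regime: str | None       # "natural" | "intervention" | None (disease-free)
    program: bool            # accrues annual lifestyle-program costs
    state0: tuple[float, ...]
    sex: str | None = None
    age: int | None = None


_HEALTHY_STATE = (1.0, 0.0, 0.0, 0.0, 0.0)


def assign_management(cascade: CascadeResult, response_rate: float,
                      initial_distribution: Sequence[float],
                      sex: str | None = None) -> list[CohortSlice]:
    """Seed Markov slices from the decision-tree arms.

    True positives split into responders (intervention regime) and
    non-responders (natural history); both attend the program and accrue its
    costs.  False positives attend the program but are disease-free and never
    transition.  Missed disease (fn, WHtR-negative diseased) follows natural
    history untreated.  Slices with zero mass are dropped.
    """
    if not (0.0 <= response_rate <= 1.0):
        raise ValueError("response_rate must be in [0, 1]")
    init = tuple(float(x) for x in initial_distribution)
    age = cascade.age
    seeds = [
        CohortSlice("tp_responder", cascade.tp * response_rate, True,
                    "intervention", True, init, sex, age),
        CohortSlice("tp_nonresponder", cascade.tp * (1.0 - response_rate), True,
                    "natural", True, init, sex, age),
        CohortSlice("fn", cascade.fn, True, "natural", False, init, sex, age),
        CohortSlice("whtr_neg_diseased", cascade.whtr_neg_diseased, True,
                    "natural", False, init, sex, age),
        CohortSlice("fp", cascade.fp, False, None, True, _HEALTHY_STATE, sex, age),
        CohortSlice("tn", cascade.tn, False, None, False, _HEALTHY_STATE, sex, age),
        CohortSlice("whtr_neg_healthy", cascade.whtr_neg_healthy, False, None,
                    False, _HEALTHY_STATE, sex, age),
    ]
    return [s for s in seeds if s.fraction > 0.0]
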