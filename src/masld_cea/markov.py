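"""Annual-cycle Markov engine over the five fibrosis states F0-F4.

The disease model is a life-table (deterministic cohort) chain on
(F0, F1, F2, F3, F4), F4 read as compensated cirrhosis.  Each annual cycle a
child remains, progresses one stage, or regresses one stage, so every
transition matrix is tridiagonal and row-stochastic.  Natural history uses
sex-specific progression probabilities and a uniform 6%/year regression;
responders to the lifestyle-modification program regress at 27.7%/year with
progression unchanged.  There is no death or other absorbing exit state over
the 10-year horizon, so occupancy mass is conserved exactly.

Scenario flags modify the matrices: a reduced treatment response in advanced
fibrosis (F3/F4 treated regression scaled by 0.75), and adolescent
modifiers (ages >= 15: progression scaled up, regression scaled down).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .cascade import CohortSlice
    from .params import ParameterSet, TransitionParams

__all__ = [
    "STAGES",
    "ScenarioFlags",
    "InvalidMatrixError",
    "build_transition_matrix",
    "step",
    "Trajectory",
    "run_horizon",
    "validate_transition_matrix",
    "validate_state_vector",
]

STAGES = ("F0", "F1", "F2", "F3", "F4")
REGIMES = ("natural", "intervention")
_MASS_TOL = 1e-12


class InvalidMatrixError(ValueError):
    """Progression + regression exceed 1 in some state."""


@dataclass(frozen=True)
class ScenarioFlags:
    """Structural scenario switches applied when building matrices.

    reduced_advanced_response
        Scale the on-treatment regression probability in F3/F4 by the
        configured multiplier (default 0.75), reflecting limited mobility
        and reduced responsiveness in advanced fibrosis.
    adolescent_transitions
        For cycles where the child is aged >= 15, scale progression up and
        regression down (default +25% / -25%; magnitudes configurable since
        only the direction is established).
    """

    reduced_advanced_response: bool = False
    adolescent_transitions: bool = False
    adolescent_progression_scale: float = 1.25
    adolescent_regression_scale: float = 0.75
    adolescent_age: int = 15


def validate_state_vector(state: np.ndarray) -> None:
    state = np.asarray(state, dtype=float)
    if state.shape != (5,):
        raise ValueError("state vector must have 5 entries (F0..F4)")
    if np.any(state < -_MASS_TOL):
        raise ValueError("state vector entries must be >= 0")
    if abs(state.sum() - 1.0) > 1e-9:
        raise ValueError(f"state vector must sum to 1, got {state.sum()!r}")


def validate_transition_matrix(matrix: np.ndarray) -> None:
    """Check row-stochasticity, nonnegativity, and tridiagonal structure."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (5, 5):
        raise ValueError("transition matrix must be 5x5")
    if np.any(m < 0.0) or np.any(m > 1.0):
        raise InvalidMatrixError("entries must lie in [0, 1]")
    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
        raise InvalidMatrixError("rows must sum to 1")
    off = ~(np.abs(np.subtract.outer(np.arange(5), np.arange(5))) <= 1)
    if np.any(m[off] != 0.0):
        raise InvalidMatrixError("only remain/progress/regress moves are allowed")


def build_transition_matrix(sex: str, regime: str, age_at_cycle: int,
                            tparams: "TransitionParams",
                            flags: ScenarioFlags = ScenarioFlags()) -> np.ndarray:
    """Assemble the annual 5x5 matrix for one sex, regime, and cycle age.

    Rows are source stages F0..F4.  F0 has no regression and F4 no
    progression; diagonals are fixed by conservation.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    prog = tparams.progression(sex).means().copy()  # moves F0->F1 .. F3->F4
    base_reg = (tparams.treated_regression if regime == "intervention"
                else tparams.regression)
    reg = np.full(4, base_reg)  # moves F1->F0 .. F4->F3
    if regime == "intervention" and flags.reduced_advanced_response:
        reg[2:] *= tparams.advanced_response_multiplier
    if flags.adolescent_transitions and age_at_cycle >= flags.adolescent_age:
        prog *= flags.adolescent_progression_scale
        reg *= flags.adolescent_regression_scale

    m = np.zeros((5, 5))
    m[0, 1] = prog[0]
    for k in (1, 2, 3):
        m[k, k - 1] = reg[k - 1]
        m[k, k + 1] = prog[k]
    m[4, 3] = reg[3]
    stay = 1.0 - m.sum(axis=1)
    if np.any(stay < -_MASS_TOL):
        raise InvalidMatrixError(
            f"progression + regression > 1 for sex={sex}, regime={regime}")
    np.fill_diagonal(m, np.clip(stay, 0.0, 1.0))
    return m


def step(state: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """One annual cycle: left-multiply the occupancy row vector."""
    return np.asarray(state, dtype=float) @ np.asarray(matrix, dtype=float)


@dataclass
class Trajectory:
    """State occupancy at cycles 0..horizon for one cohort slice."""

    states: np.ndarray  # (horizon + 1, 5)
    arm: str = ""
    sex: str | None = None
    age: int | None = None
    fraction: float = 1.0

    @property
    def horizon(self) -> int:
        return self.states.shape[0] - 1

    def occupancy(self, stage: int) -> np.ndarray:
        return self.states[:, stage]


MatrixProvider = Callable[[str, str, int], np.ndarray]


def run_horizon(seed_slice: "CohortSlice", params: "ParameterSet",
                flags: ScenarioFlags = ScenarioFlags(),
                horizon: int | None = None,
                matrix_provider: MatrixProvider | None = None) -> Trajectory:
    """Evolve one slice over the horizon, rebuilding the matrix as it ages.

    Disease-free slices (false positives, true negatives, healthy
    screen-negatives) have nothing to transition and return a constant
    trajectory.  A child baseline-aged ``a`` transitions through cycle t
    (from t-1 to t) at age ``a + t - 1``.
    """
    H = params.horizon_years if horizon is None else horizon
    if H < 0:
        raise ValueError("horizon must be >= 0")
    state = np.asarray(seed_slice.state0, dtype=float)
    validate_state_vector(state)
    states = np.empty((H + 1, 5))
    states[0] = state
    if not seed_slice.diseased:
        states[1:] = state
    else:
        provider = matrix_provider or (
            lambda sex, regime, age: build_transition_matrix(
                sex, regime, age, params.transitions, flags))
        sex = seed_slice.sex or "boys"
        regime = seed_slice.regime or "natural"
        age0 = seed_slice.age if seed_slice.age is not None else 6
        for t in range(1, H + 1):
            m = provider(sex, regime, age0 + t - 1)
            state = state @ m
            states[t] = state
    return Trajectory(states=states, arm=seed_slice.arm, sex=seed_slice.sex,
                      age=seed_slice.age, fraction=seed_slice.fraction)
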