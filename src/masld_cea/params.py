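"""Model parameters for the pediatric MASLD screening cost-utility model.

Every input of the decision model lives here: second-stage test performance,
the baseline fibrosis-stage distribution, costs (2019 USD), per-stage
utilities, annual fibrosis transition probabilities by sex, and run settings
(discount rate, horizon, cohort size, willingness-to-pay thresholds).

Uncertain inputs are represented as :class:`UncertainValue` — a point
estimate with a 95% interval and a distribution kind.  Beta distributions
are fitted from (mean, 95% CI) by method of moments with a
normal-approximate standard deviation, sigma = (ci_high - ci_low) / (2 * 1.96):

    nu    = mean * (1 - mean) / sigma**2 - 1
    alpha = mean * nu
    beta  = (1 - mean) * nu

which preserves the analytic mean exactly.  Costs and a handful of
probabilities without printed intervals are ``fixed`` (point mass) in the
probabilistic sensitivity analysis.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Any, Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "UncertainValue",
    "TestPerformance",
    "CostSchedule",
    "UtilitySchedule",
    "ProgressionRates",
    "TransitionParams",
    "ParameterSet",
    "beta_from_ci",
    "default_parameters",
    "load_config",
    "save_config",
    "DegenerateIntervalError",
    "BetaFitError",
    "ConfigError",
]

Z95 = 1.96  # normal quantile used to back out sigma from a 95% interval

TEST_NAMES = ("ultrasound", "fibroscan", "mri_pdff")
SEXES = ("boys", "girls")
STAGES = ("F0", "F1", "F2", "F3", "F4")


class DegenerateIntervalError(ValueError):
    """Zero-width interval: the value is fixed, not a distribution."""


class BetaFitError(ValueError):
    """The implied variance is incompatible with a Beta distribution."""


class ConfigError(ValueError):
    """A run configuration violates a structural invariant."""


def beta_from_ci(mean: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Fit Beta(alpha, beta) shapes from a mean and 95% interval by moments.

    Raises
    ------
    DegenerateIntervalError
        If ``ci_low == ci_high`` (a fixed value, not a distribution).
    BetaFitError
        If the implied variance is >= mean*(1-mean), which no Beta attains.
    """
    if not (0.0 <= ci_low <= mean <= ci_high <= 1.0):
        raise ValueError(
            f"require 0 <= ci_low <= mean <= ci_high <= 1, got "
            f"({mean}, {ci_low}, {ci_high})"
        )
    if ci_high == ci_low:
        raise DegenerateIntervalError("zero-width interval signals a fixed value")
    sigma = (ci_high - ci_low) / (2.0 * Z95)
    var = sigma * sigma
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise BetaFitError(
            f"implied variance {var:.6g} >= mean*(1-mean) = {bound:.6g}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class UncertainValue:
    """A model input with a point estimate and an uncertainty specification.

    ``dist_kind`` is ``"beta"`` for probabilities/utilities with a printed
    95% interval, or ``"fixed"`` for point-mass inputs (costs, and
    probabilities reported without intervals).
    """

    mean: float
    ci_low: float
    ci_high: float
    dist_kind: str = "beta"

    def __post_init__(self) -> None:
        if self.dist_kind not in ("beta", "fixed"):
            raise ValueError(f"unknown dist_kind {self.dist_kind!r}")
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError(
                f"require ci_low <= mean <= ci_high, got "
                f"({self.ci_low}, {self.mean}, {self.ci_high})"
            )
        if self.dist_kind == "fixed":
            if not (self.ci_low == self.mean == self.ci_high):
                raise ValueError("fixed values must have ci_low == mean == ci_high")
        else:
            if not (0.0 <= self.ci_low and self.ci_high <= 1.0):
                raise ValueError("beta-kind values must lie in [0, 1]")

    @classmethod
    def fixed(cls, value: float) -> "UncertainValue":
        return cls(value, value, value, "fixed")

    @classmethod
    def beta(cls, mean: float, ci_low: float, ci_high: float) -> "UncertainValue":
        return cls(mean, ci_low, ci_high, "beta")

    @property
    def is_fixed(self) -> bool:
        return self.dist_kind == "fixed" or self.ci_low == self.ci_high

    def beta_shapes(self) -> tuple[float, float]:
        return beta_from_ci(self.mean, self.ci_low, self.ci_high)

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the fitted distribution (point mass if fixed)."""
        if self.is_fixed:
            return self.mean if size is None else np.full(size, self.mean)
        a, b = self.beta_shapes()
        return rng.beta(a, b, size=size)

    def point(self) -> "UncertainValue":
        """Collapse to a fixed value at the point estimate."""
        return UncertainValue.fixed(self.mean)


def _uv(mean, lo=None, hi=None) -> UncertainValue:
    if lo is None:
        return UncertainValue.fixed(mean)
    return UncertainValue.beta(mean, lo, hi)


@dataclass(frozen=True)
class TestPerformance:
    """Sensitivity/specificity of a second-stage imaging test in children."""

    test_name: str
    sensitivity: UncertainValue
    specificity: UncertainValue

    def __post_init__(self) -> None:
        if self.test_name not in TEST_NAMES:
            raise ValueError(f"unknown test {self.test_name!r}")


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs in 2019 USD (healthcare-system perspective)."""

    routine_exam: float = 2.9
    ultrasound: float = 16.5
    fibroscan: float = 13.0
    mri_pdff: float = 87.0
    blood_panel: float = 22.5
    program_fixed_annual: float = 10.5
    program_variable_annual: float = 21.7

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"cost {f.name} must be >= 0")

    def second_stage(self, test_name: str) -> float:
        return {"ultrasound": self.ultrasound, "fibroscan": self.fibroscan,
                "mri_pdff": self.mri_pdff}[test_name]

    @property
    def program_annual(self) -> float:
        return self.program_fixed_annual + self.program_variable_annual


@dataclass(frozen=True)
class UtilitySchedule:
    """Per-stage health-state utilities.

    F1 and F2 share a single utility (same source estimate); they are drawn
    jointly in the probabilistic sensitivity analysis.
    """

    f0: UncertainValue
    f1_f2: UncertainValue
    f3: UncertainValue
    f4: UncertainValue

    @property
    def f1(self) -> UncertainValue:
        return self.f1_f2

    @property
    def f2(self) -> UncertainValue:
        return self.f1_f2

    def point_vector(self) -> np.ndarray:
        """Utility weights over (F0, F1, F2, F3, F4)."""
        return np.array([self.f0.mean, self.f1_f2.mean, self.f1_f2.mean,
                         self.f3.mean, self.f4.mean])

    def check_ordering(self) -> None:
        u = self.point_vector()
        if not (u[0] >= u[1] >= u[3] >= u[4]):
            raise ConfigError(
                "utility point estimates must satisfy "
                "u(F0) >= u(F1)=u(F2) >= u(F3) >= u(F4)"
            )


@dataclass(frozen=True)
class ProgressionRates:
    """Annual one-stage progression probabilities for one sex."""

    f0_to_f1: UncertainValue
    f1_to_f2: UncertainValue
    f2_to_f3: UncertainValue
    f3_to_f4: UncertainValue

    def means(self) -> np.ndarray:
        return np.array([self.f0_to_f1.mean, self.f1_to_f2.mean,
                         self.f2_to_f3.mean, self.f3_to_f4.mean])

    def as_tuple(self) -> tuple[UncertainValue, ...]:
        return (self.f0_to_f1, self.f1_to_f2, self.f2_to_f3, self.f3_to_f4)


@dataclass(frozen=True)
class TransitionParams:
    """Annual fibrosis transition rules.

    Natural history: sex-specific one-stage progression (Table of annual
    probabilities) and a uniform 6% one-stage regression.  Responders to the
    lifestyle-modification program regress at 27.7%/year instead, with
    progression unchanged; the program is effective in ``response_rate`` of
    participants.  ``advanced_response_multiplier`` scales the treated
    regression in F3/F4 under the reduced-advanced-response scenario.
    """

    boys: ProgressionRates
    girls: ProgressionRates
    regression: float = 0.06
    treated_regression: float = 0.277
    response_rate: float = 0.40
    advanced_response_multiplier: float = 0.75

    def __post_init__(self) -> None:
        for name in ("regression", "treated_regression", "response_rate",
                     "advanced_response_multiplier"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def progression(self, sex: str) -> ProgressionRates:
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        return getattr(self, sex)

    def validate_rows(self) -> None:
        for sex in SEXES:
            prog = self.progression(sex).means()
            for reg in (self.regression, self.treated_regression):
                # F1..F3 rows carry both a progression and a regression move
                if np.any(prog[1:] + reg > 1.0):
                    raise ConfigError(
                        f"progression + regression > 1 for {sex}"
                    )


@dataclass(frozen=True)
class ParameterSet:
    """The complete registry of model inputs for one run."""

    tests: Mapping[str, TestPerformance]
    initial_stage_distribution: tuple[float, ...]
    prevalence_by_age: Mapping[int, float]
    costs: CostSchedule
    utilities: UtilitySchedule
    transitions: TransitionParams
    whtr_positivity: float = 0.226
    whtr_stage1_sensitivity: float = 1.0
    discount_rate: float = 0.03
    horizon_years: int = 10
    cohort_size: int = 100_000
    program_duration_years: int | None = None  # None -> full horizon
    blood_panel_all_whtr_positive: bool = True
    wtp_thresholds: tuple[float, ...] = (30584.0, 71415.5)

    def validate(self, check_utility_ordering: bool = True) -> "ParameterSet":
        """Check all structural invariants; returns self for chaining."""
        for key in ("whtr_positivity", "whtr_stage1_sensitivity"):
            v = getattr(self, key)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{key} must be in [0, 1], got {v}")
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        if self.horizon_years < 1:
            raise ConfigError("horizon_years must be >= 1")
        if self.cohort_size < 1:
            raise ConfigError("cohort_size must be >= 1")
        if self.program_duration_years is not None and not (
                1 <= self.program_duration_years <= self.horizon_years):
            raise ConfigError("program_duration_years must be in 1..horizon")
        dist = np.asarray(self.initial_stage_distribution, dtype=float)
        if dist.shape != (5,) or np.any(dist < 0):
            raise ConfigError("initial_stage_distribution must be 5 nonnegative fractions")
        if abs(dist.sum() - 1.0) > 1e-12:
            raise ConfigError("initial_stage_distribution must sum to 1")
        for age, p in self.prevalence_by_age.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"prevalence_by_age[{age}] must be in [0, 1], got {p}")
        for t in self.tests.values():
            for uv in (t.sensitivity, t.specificity):
                if not (0.0 <= uv.mean <= 1.0):
                    raise ConfigError(f"test performance for {t.test_name} out of [0, 1]")
        for name, uv in self.iter_uncertain():
            # utilities and probabilities stay in [0, 1] even when a config
            # pins them to a fixed value
            if not (0.0 <= uv.mean <= 1.0):
                raise ConfigError(f"{name} out of [0, 1]")
        if check_utility_ordering:
            self.utilities.check_ordering()
        self.transitions.validate_rows()
        if any(w <= 0 for w in self.wtp_thresholds):
            raise ConfigError("wtp_thresholds must be positive")
        return self

    @property
    def program_duration(self) -> int:
        return (self.program_duration_years
                if self.program_duration_years is not None
                else self.horizon_years)

    def prevalence(self, age: int) -> float:
        try:
            return float(self.prevalence_by_age[age])
        except KeyError:
            raise ConfigError(f"no prevalence configured for age {age}") from None

    def initial_state(self) -> np.ndarray:
        return np.asarray(self.initial_stage_distribution, dtype=float)

    def iter_uncertain(self) -> Iterator[tuple[str, UncertainValue]]:
        """Yield (dotted-name, UncertainValue) for every uncertain input."""
        for name in TEST_NAMES:
            t = self.tests[name]
            yield f"tests.{name}.sensitivity", t.sensitivity
            yield f"tests.{name}.specificity", t.specificity
        yield "utilities.f0", self.utilities.f0
        yield "utilities.f1_f2", self.utilities.f1_f2
        yield "utilities.f3", self.utilities.f3
        yield "utilities.f4", self.utilities.f4
        for sex in SEXES:
            prog = self.transitions.progression(sex)
            for move in ("f0_to_f1", "f1_to_f2", "f2_to_f3", "f3_to_f4"):
                yield f"transitions.{sex}.{move}", getattr(prog, move)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "whtr_positivity": self.whtr_positivity,
            "whtr_stage1_sensitivity": self.whtr_stage1_sensitivity,
            "discount_rate": self.discount_rate,
            "horizon_years": self.horizon_years,
            "cohort_size": self.cohort_size,
            "program_duration_years": self.program_duration_years,
            "blood_panel_all_whtr_positive": self.blood_panel_all_whtr_positive,
            "wtp_thresholds": list(self.wtp_thresholds),
            "initial_stage_distribution": list(self.initial_stage_distribution),
            "prevalence_by_age": {int(a): float(p)
                                  for a, p in sorted(self.prevalence_by_age.items())},
            "tests": {
                name: {
                    "sensitivity": _uv_to_dict(self.tests[name].sensitivity),
                    "specificity": _uv_to_dict(self.tests[name].specificity),
                }
                for name in TEST_NAMES
            },
            "costs": {f.name: getattr(self.costs, f.name)
                      for f in fields(CostSchedule)},
            "utilities": {
                "f0": _uv_to_dict(self.utilities.f0),
                "f1_f2": _uv_to_dict(self.utilities.f1_f2),
                "f3": _uv_to_dict(self.utilities.f3),
                "f4": _uv_to_dict(self.utilities.f4),
            },
            "transitions": {
                "regression": self.transitions.regression,
                "treated_regression": self.transitions.treated_regression,
                "response_rate": self.transitions.response_rate,
                "advanced_response_multiplier":
                    self.transitions.advanced_response_multiplier,
                **{sex: {move: _uv_to_dict(getattr(self.transitions.progression(sex), move))
                         for move in ("f0_to_f1", "f1_to_f2", "f2_to_f3", "f3_to_f4")}
                   for sex in SEXES},
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any],
                  base: "ParameterSet | None" = None,
                  check_utility_ordering: bool = True) -> "ParameterSet":
        """Build a ParameterSet from a nested dict, falling back to ``base``
        (the package defaults when omitted) for any absent key."""
        if base is None:
            base = default_parameters()
        merged = _deep_merge(base.to_dict(), dict(data), path="")
        try:
            ps = cls(
                whtr_positivity=float(merged["whtr_positivity"]),
                whtr_stage1_sensitivity=float(merged["whtr_stage1_sensitivity"]),
                discount_rate=float(merged["discount_rate"]),
                horizon_years=int(merged["horizon_years"]),
                cohort_size=int(merged["cohort_size"]),
                program_duration_years=(
                    None if merged["program_duration_years"] is None
                    else int(merged["program_duration_years"])),
                blood_panel_all_whtr_positive=bool(
                    merged["blood_panel_all_whtr_positive"]),
                wtp_thresholds=tuple(float(w) for w in merged["wtp_thresholds"]),
                initial_stage_distribution=tuple(
                    float(x) for x in merged["initial_stage_distribution"]),
                prevalence_by_age={int(a): float(p)
                                   for a, p in merged["prevalence_by_age"].items()},
                tests={name: TestPerformance(
                    name,
                    _uv_from_dict(merged["tests"][name]["sensitivity"],
                                  f"tests.{name}.sensitivity"),
                    _uv_from_dict(merged["tests"][name]["specificity"],
                                  f"tests.{name}.specificity"))
                    for name in TEST_NAMES},
                costs=CostSchedule(**{f.name: float(merged["costs"][f.name])
                                      for f in fields(CostSchedule)}),
                utilities=UtilitySchedule(
                    f0=_uv_from_dict(merged["utilities"]["f0"], "utilities.f0"),
                    f1_f2=_uv_from_dict(merged["utilities"]["f1_f2"], "utilities.f1_f2"),
                    f3=_uv_from_dict(merged["utilities"]["f3"], "utilities.f3"),
                    f4=_uv_from_dict(merged["utilities"]["f4"], "utilities.f4")),
                transitions=TransitionParams(
                    boys=_prog_from_dict(merged["transitions"]["boys"], "boys"),
                    girls=_prog_from_dict(merged["transitions"]["girls"], "girls"),
                    regression=float(merged["transitions"]["regression"]),
                    treated_regression=float(
                        merged["transitions"]["treated_regression"]),
                    response_rate=float(merged["transitions"]["response_rate"]),
                    advanced_response_multiplier=float(
                        merged["transitions"]["advanced_response_multiplier"])),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        return ps.validate(check_utility_ordering=check_utility_ordering)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _uv_to_dict(uv: UncertainValue) -> dict:
    if uv.dist_kind == "fixed":
        return {"value": uv.mean}
    return {"mean": uv.mean, "ci": [uv.ci_low, uv.ci_high], "dist": "beta"}


def _uv_from_dict(d: Any, key: str) -> UncertainValue:
    if isinstance(d, (int, float)):
        return UncertainValue.fixed(float(d))
    if not isinstance(d, Mapping):
        raise ConfigError(f"{key}: expected a number or mapping, got {d!r}")
    try:
        if "value" in d:
            return UncertainValue.fixed(float(d["value"]))
        mean = float(d["mean"])
        if "ci" in d and d["ci"] is not None:
            lo, hi = (float(x) for x in d["ci"])
            return UncertainValue(mean, lo, hi, str(d.get("dist", "beta")))
        return UncertainValue.fixed(mean)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{key}: {exc}") from exc


def _prog_from_dict(d: Mapping, sex: str) -> ProgressionRates:
    return ProgressionRates(**{
        move: _uv_from_dict(d[move], f"transitions.{sex}.{move}")
        for move in ("f0_to_f1", "f1_to_f2", "f2_to_f3", "f3_to_f4")})


def _is_uv_spec(node) -> bool:
    return isinstance(node, Mapping) and ("mean" in node or "value" in node)


def _deep_merge(base: dict, override: Mapping, path: str) -> dict:
    out = dict(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            warnings.warn(f"unknown config key {here!r} ignored", stacklevel=2)
            continue
        if _is_uv_spec(base[key]):
            # an uncertain-value spec is replaced wholesale, never key-merged:
            # {"value": 0.9} must not inherit the default's mean/ci
            out[key] = value
        elif isinstance(base[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(base[key], value, here)
        else:
            out[key] = value
    return out


def default_parameters() -> ParameterSet:
    """The base-case parameter set.

    Point estimates and intervals reproduce the published base case: test
    performance and utilities with Beta uncertainty, fixed costs, the
    baseline fibrosis-stage split among diseased children, annual
    sex-specific progression with 6% natural / 27.7% on-treatment regression,
    a 3% discount rate, a 10-year horizon and a 100,000-child cohort.  The
    age-specific MASLD prevalence has no published point values and is filled
    from the synthetic logistic-in-age profile (see
    :func:`masld_cea.cohort.synth_prevalence`).
    """
    from .cohort import synth_prevalence  # local import: avoids module cycle

    tests = {
        "ultrasound": TestPerformance(
            "ultrasound", _uv(0.52, 0.41, 0.64), _uv(0.96, 0.91, 0.99)),
        "fibroscan": TestPerformance(
            "fibroscan", _uv(0.72, 0.64, 0.79), _uv(0.98, 0.97, 0.98)),
        "mri_pdff": TestPerformance(
            "mri_pdff", _uv(0.95, 0.92, 0.97), _uv(0.92, 0.77, 0.98)),
    }
    utilities = UtilitySchedule(
        f0=_uv(0.95, 0.93, 1.00),
        f1_f2=_uv(0.85, 0.79, 0.92),
        f3=_uv(0.73, 0.64, 0.82),
        f4=_uv(0.66, 0.49, 0.83),
    )
    transitions = TransitionParams(
        boys=ProgressionRates(
            f0_to_f1=_uv(0.004, 0.002, 0.006),
            f1_to_f2=_uv(0.033, 0.020, 0.051),
            f2_to_f3=_uv(0.033, 0.020, 0.051),
            f3_to_f4=_uv(0.034, 0.019, 0.064)),
        girls=ProgressionRates(
            f0_to_f1=_uv(0.003, 0.002, 0.005),
            f1_to_f2=_uv(0.028, 0.016, 0.043),
            f2_to_f3=_uv(0.028, 0.016, 0.043),
            f3_to_f4=_uv(0.028, 0.016, 0.054)),
    )
    ps = ParameterSet(
        tests=tests,
        initial_stage_distribution=(0.885, 0.052, 0.035, 0.016, 0.012),
        prevalence_by_age=synth_prevalence().by_age,
        costs=CostSchedule(),
        utilities=utilities,
        transitions=transitions,
    )
    return ps.validate()


def load_config(path) -> ParameterSet:
    """Load a YAML run configuration; absent keys fall back to defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return ParameterSet.from_dict(data)


def save_config(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def with_override(params: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with one dotted-path input set to ``value``.

    For uncertain inputs the point estimate is replaced by a fixed value,
    which is how one-way and scenario analyses re-run the model at a bound.
    Structural invariants are re-checked, except the utility-ordering
    convention (a bound may legitimately cross a neighbouring stage).
    """
    d = params.to_dict()
    node = d
    parts = path.split(".")

    def _key(container: dict, token: str):
        if token in container:
            return token
        if token.lstrip("-").isdigit() and int(token) in container:
            return int(token)  # e.g. prevalence_by_age.10
        raise KeyError(f"unknown parameter path {path!r}")

    for p in parts[:-1]:
        node = node[_key(node, p)]
    leaf = _key(node, parts[-1])
    if isinstance(node[leaf], dict) and ("mean" in node[leaf] or "value" in node[leaf]):
        node[leaf] = {"value": float(value)}
    else:
        node[leaf] = value
    return ParameterSet.from_dict(d, base=params, check_utility_ordering=False)
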