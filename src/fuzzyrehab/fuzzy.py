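"""Mamdani fuzzy inference: fuzzification, rule firing, aggregation, centroid.

The engine is deliberately minimal: rules are pure conjunctions (min
t-norm), consequents are clipped at their rule's firing strength
(min implication), clipped sets are combined pointwise by max, and the
aggregate is defuzzified by its centroid on a uniform grid.  Sugeno
systems, OR/NOT connectives and hedges are out of scope.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, DomainError

#: Wildcard antecedent: the rule does not constrain this variable.
ANY = "Any"


class MFShape(str, Enum):
    triangular = "triangular"
    trapezoidal = "trapezoidal"
    crisp_singleton = "crisp_singleton"


_N_BREAKPOINTS = {
    MFShape.triangular: 3,
    MFShape.trapezoidal: 4,
    MFShape.crisp_singleton: 1,
}


class MembershipFunction(BaseModel):
    """A named fuzzy set over one variable's universe.

    ``breakpoints`` are the ordered abscissae of the shape: 3 for a
    triangle (left foot, peak, right foot), 4 for a trapezoid (left
    foot, left shoulder, right shoulder, right foot), 1 for a crisp
    singleton.  Degenerate (vertical) edges are allowed, e.g. a
    left-shoulder trapezoid ``(0, 0, 20, 45)``.
    """

    model_config = ConfigDict(frozen=True)

    label: str
    shape: MFShape
    breakpoints: tuple[float, ...]

    @model_validator(mode="after")
    def _check(self) -> "MembershipFunction":
        want = _N_BREAKPOINTS[self.shape]
        if len(self.breakpoints) != want:
            raise ValueError(
                f"{self.shape.value} membership function {self.label!r} needs "
                f"{want} breakpoints, got {len(self.breakpoints)}"
            )
        if any(b < a for a, b in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError(
                f"breakpoints of {self.label!r} must be non-decreasing"
            )
        return self

    def degree(self, x: float | np.ndarray) -> float | np.ndarray:
        """Membership degree at ``x`` (scalar or array), in [0, 1]."""
        x = np.asarray(x, dtype=float)
        if self.shape is MFShape.crisp_singleton:
            out = (x == self.breakpoints[0]).astype(float)
        elif self.shape is MFShape.triangular:
            a, b, c = self.breakpoints
            out = np.minimum(_rising(x, a, b), _falling(x, b, c))
        else:
            a, b, c, d = self.breakpoints
            out = np.minimum(_rising(x, a, b), _falling(x, c, d))
        return float(out) if out.ndim == 0 else out

    @property
    def support(self) -> tuple[float, float]:
        return self.breakpoints[0], self.breakpoints[-1]


def _rising(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Edge from degree 0 at ``a`` to 1 at ``b``; vertical if a == b."""
    if b > a:
        return np.clip((x - a) / (b - a), 0.0, 1.0)
    return (x >= a).astype(float)


def _falling(x: np.ndarray, a: float, b: float) -> np.ndarray:
    if b > a:
        return np.clip((b - x) / (b - a), 0.0, 1.0)
    return (x <= b).astype(float)


class LinguisticVariable(BaseModel):
    """A named variable with a closed universe and a set of labelled fuzzy sets."""

    model_config = ConfigDict(frozen=True)

    name: str
    universe: tuple[float, float]
    units: str = ""
    labels: tuple[MembershipFunction, ...]

    @model_validator(mode="after")
    def _check(self) -> "LinguisticVariable":
        lo, hi = self.universe
        if not lo < hi:
            raise ValueError(f"universe of {self.name!r} must satisfy lo < hi")
        names = [mf.label for mf in self.labels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate label names in variable {self.name!r}")
        if not self.labels:
            raise ValueError(f"variable {self.name!r} has no labels")
        for mf in self.labels:
            if mf.breakpoints[0] < lo or mf.breakpoints[-1] > hi:
                raise ValueError(
                    f"label {mf.label!r} of {self.name!r} leaves the universe "
                    f"[{lo}, {hi}]"
                )
        return self

    def label(self, name: str) -> MembershipFunction:
        for mf in self.labels:
            if mf.label == name:
                return mf
        raise ConfigurationError(
            f"variable {self.name!r} has no label {name!r}"
        )

    @property
    def label_names(self) -> tuple[str, ...]:
        return tuple(mf.label for mf in self.labels)

    def clamp(self, x: float) -> float:
        lo, hi = self.universe
        return min(max(x, lo), hi)

    def membership_degree(self, label: str, x: float) -> float:
        """Degree of ``x`` under ``label``; raises if ``x`` leaves the universe."""
        lo, hi = self.universe
        if not (lo <= x <= hi):
            raise DomainError(
                f"value {x} outside universe [{lo}, {hi}] of variable "
                f"{self.name!r}"
            )
        return float(self.label(label).degree(x))

    def fuzzify(self, x: float) -> dict[str, float]:
        """Map a crisp value to one degree per label.

        Out-of-universe values are clamped to the nearest endpoint so a
        sensor glitch can never crash the control loop.
        """
        x = self.clamp(float(x))
        return {mf.label: float(mf.degree(x)) for mf in self.labels}

    def grid(self, resolution: int) -> np.ndarray:
        return np.linspace(self.universe[0], self.universe[1], resolution)

    def coverage_gaps(self, resolution: int = 201) -> list[float]:
        """Grid points where no label has positive degree (should be empty)."""
        g = self.grid(resolution)
        covered = np.zeros_like(g, dtype=bool)
        for mf in self.labels:
            covered |= np.asarray(mf.degree(g)) > 0
        return [float(v) for v in g[~covered]]


class FuzzyRule(BaseModel):
    """If-Then rule: conjunction of per-variable label conditions.

    An antecedent value of :data:`ANY` leaves that variable
    unconstrained (it contributes degree 1 to the conjunction).
    """

    model_config = ConfigDict(frozen=True)

    antecedents: Mapping[str, str]
    consequent: str

    @model_validator(mode="after")
    def _check(self) -> "FuzzyRule":
        if all(v == ANY for v in self.antecedents.values()):
            raise ValueError("a rule must constrain at least one variable")
        return self


class FISConfig(BaseModel):
    """A complete Mamdani system: inputs, one output, rule base."""

    model_config = ConfigDict(frozen=True)

    name: str
    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: tuple[FuzzyRule, ...]
    defuzz_resolution: int = 1001
    default_output_label: str
    #: Preference order for breaking exact membership ties when mapping the
    #: crisp centroid back to a label; earlier wins.  Defaults to the output
    #: variable's declaration order.
    tie_break: Optional[tuple[str, ...]] = None

    @model_validator(mode="after")
    def _check(self) -> "FISConfig":
        if self.defuzz_resolution < 101:
            raise ValueError("defuzz_resolution must be >= 101")
        by_name = {v.name: v for v in self.inputs}
        if len(by_name) != len(self.inputs):
            raise ValueError(f"duplicate input variable names in {self.name!r}")
        for i, rule in enumerate(self.rules):
            for var, lab in rule.antecedents.items():
                if var not in by_name:
                    raise ValueError(
                        f"rule {i} of {self.name!r} references unknown "
                        f"variable {var!r}"
                    )
                if lab != ANY and lab not in by_name[var].label_names:
                    raise ValueError(
                        f"rule {i} of {self.name!r} references unknown label "
                        f"{lab!r} of variable {var!r}"
                    )
            if rule.consequent not in self.output.label_names:
                raise ValueError(
                    f"rule {i} of {self.name!r} has unknown consequent "
                    f"{rule.consequent!r}"
                )
        if self.default_output_label not in self.output.label_names:
            raise ValueError(
                f"default_output_label {self.default_output_label!r} is not a "
                f"label of {self.output.name!r}"
            )
        if self.tie_break is not None and set(self.tie_break) != set(
            self.output.label_names
        ):
            raise ValueError("tie_break must be a permutation of output labels")
        return self

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.inputs)

    def input_variable(self, name: str) -> LinguisticVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise ConfigurationError(f"{self.name!r} has no input variable {name!r}")


class InferenceResult(BaseModel):
    """Outcome of one crisp evaluation of a FIS."""

    model_config = ConfigDict(frozen=True)

    value: Optional[float]  # None when no rule fired
    label: str
    activated: bool
    strengths: tuple[float, ...]  # per rule, in rule order


def membership_degree(
    var: LinguisticVariable, label: str, x: float
) -> float:
    """Degree of crisp ``x`` under one label of ``var`` (strict domain check)."""
    return var.membership_degree(label, x)


def fuzzify(var: LinguisticVariable, x: float) -> dict[str, float]:
    return var.fuzzify(x)


def rule_firing_strength(
    rule: FuzzyRule, fuzzified: Mapping[str, Mapping[str, float]]
) -> float:
    """min over non-ANY antecedent degrees (ANY contributes 1)."""
    strength = 1.0
    for var, lab in rule.antecedents.items():
        if lab == ANY:
            continue
        if var not in fuzzified:
            raise ConfigurationError(
                f"rule references variable {var!r} missing from fuzzified inputs"
            )
        strength = min(strength, fuzzified[var][lab])
    return strength


def aggregate(
    strengths: Sequence[float],
    rules: Sequence[FuzzyRule],
    output: LinguisticVariable,
    resolution: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise-max union of consequents clipped at their rule strengths.

    Returns ``(grid, mu)`` sampled uniformly over the output universe.
    """
    grid = output.grid(resolution)
    mu = np.zeros_like(grid)
    for rule, s in zip(rules, strengths):
        if s <= 0.0:
            continue
        shape = np.minimum(np.asarray(output.label(rule.consequent).degree(grid)), s)
        np.maximum(mu, shape, out=mu)
    return grid, mu


def centroid(grid: np.ndarray, mu: np.ndarray) -> Optional[float]:
    """Center of mass ∫x·μ(x)dx / ∫μ(x)dx on the sampled aggregate.

    The sampled aggregate is treated as the piecewise-linear function it
    is: the mass uses the trapezoid rule (exact for a polyline) and the
    first moment uses the exact per-cell closed form for x times a
    linear segment, so the centroid of the sampled shape carries no
    additional integration error.  Returns ``None`` when total mass is
    zero (no rule fired).
    """
    total = float(np.trapezoid(mu, grid))
    if total <= 0.0 or not math.isfinite(total):
        return None
    x0, x1 = grid[:-1], grid[1:]
    y0, y1 = mu[:-1], mu[1:]
    # ∫ x·y dx over [x0,x1] with y linear = h·(x0(2y0+y1) + x1(y0+2y1))/6
    moment = float(
        np.sum((x1 - x0) * (x0 * (2 * y0 + y1) + x1 * (y0 + 2 * y1)) / 6.0)
    )
    return moment / total


def select_label(
    fis: FISConfig, value: Optional[float]
) -> str:
    """Map a crisp output value back to the output label with maximal degree.

    Exact ties resolve by the config's ``tie_break`` preference order
    (declaration order by default).  ``None`` maps to the default label.
    """
    if value is None:
        return fis.default_output_label
    order = fis.tie_break or fis.output.label_names
    rank = {name: i for i, name in enumerate(order)}
    best_label = fis.default_output_label
    best_key = (-1.0, -math.inf)
    for mf in fis.output.labels:
        key = (float(mf.degree(value)), -rank[mf.label])
        if key > best_key:
            best_key = key
            best_label = mf.label
    return best_label


def infer(fis: FISConfig, inputs: Mapping[str, float]) -> InferenceResult:
    """Run the full Mamdani pipeline on one crisp input vector.

    ``inputs`` must carry one value per declared input variable; values
    outside a universe are clamped during fuzzification.
    """
    missing = set(fis.input_names) - set(inputs)
    if missing:
        raise ConfigurationError(
            f"{fis.name!r} is missing crisp inputs for {sorted(missing)}"
        )
    fuzzified = {v.name: v.fuzzify(inputs[v.name]) for v in fis.inputs}
    strengths = tuple(rule_firing_strength(r, fuzzified) for r in fis.rules)
    grid, mu = aggregate(strengths, fis.rules, fis.output, fis.defuzz_resolution)
    value = centroid(grid, mu)
    return InferenceResult(
        value=value,
        label=select_label(fis, value),
        activated=value is not None,
        strengths=strengths,
    )
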