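"""Rule profiles: the named bundle of both controllers' fuzzy systems.

A profile packages the help-controller FIS, the difficulty-controller
FIS and the signal parameters, so therapists can keep one
parameterization per patient group and tweak membership functions or
rules without touching code.  The shipped default profile encodes the
standard Low/Medium/High partitions and the example rule bases for both
controllers.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .fuzzy import (
    ANY,
    FISConfig,
    FuzzyRule,
    LinguisticVariable,
    MembershipFunction,
    MFShape,
)
from .signals import SignalConfig

FORMAT_VERSION = "1.0"

# --- Canonical output label names ---------------------------------------

HELP_DO_NOT_MODIFY = "do_not_modify"
HELP_ACTIVATE = "activate_help"
HELP_CANCEL = "cancel_step"

D_MINUS_MINUS = "D--"
D_MINUS = "D-"
D_EQUAL = "D="
D_PLUS = "D+"
D_PLUS_PLUS = "D++"

#: Offset semantics of the difficulty-controller output labels.
OFFSET_BY_LABEL = {
    D_MINUS_MINUS: -2,
    D_MINUS: -1,
    D_EQUAL: 0,
    D_PLUS: 1,
    D_PLUS_PLUS: 2,
}
LABEL_BY_OFFSET = {v: k for k, v in OFFSET_BY_LABEL.items()}


class RuleProfile(BaseModel):
    """Named parameterization of both controllers plus the signal pipeline."""

    model_config = ConfigDict(frozen=True)

    format_version: str = FORMAT_VERSION
    name: str = Field(min_length=1)
    fis4h: FISConfig
    fis4d: FISConfig
    signal: SignalConfig = SignalConfig()

    @model_validator(mode="after")
    def _check(self) -> "RuleProfile":
        for lab in self.fis4d.output.label_names:
            if lab not in OFFSET_BY_LABEL:
                raise ValueError(
                    f"difficulty output label {lab!r} has no offset semantics; "
                    f"expected one of {sorted(OFFSET_BY_LABEL)}"
                )
        return self


def _tri(label: str, a: float, b: float, c: float) -> MembershipFunction:
    return MembershipFunction(
        label=label, shape=MFShape.triangular, breakpoints=(a, b, c)
    )


def _trap(
    label: str, a: float, b: float, c: float, d: float
) -> MembershipFunction:
    return MembershipFunction(
        label=label, shape=MFShape.trapezoidal, breakpoints=(a, b, c, d)
    )


def three_label_partition(
    name: str, lo: float, hi: float, units: str = ""
) -> LinguisticVariable:
    """Standard overlapping Low/Medium/High partition over [lo, hi].

    The shape is the normalized pattern Low (0,0,20,45), Medium
    (30,50,70), High (55,80,100,100) scaled to the span, which gives
    full coverage and the usual ~50 % overlap between neighbours.
    """
    s = (hi - lo) / 100.0

    def at(v: float) -> float:
        return lo + v * s

    return LinguisticVariable(
        name=name,
        universe=(lo, hi),
        units=units,
        labels=(
            _trap("Low", at(0), at(0), at(20), at(45)),
            _tri("Medium", at(30), at(50), at(70)),
            _trap("High", at(55), at(80), at(100), at(100)),
        ),
    )


def yes_no_variable(name: str) -> LinguisticVariable:
    """Binary variable encoded as crisp singletons at 0 (No) and 1 (Yes)."""
    return LinguisticVariable(
        name=name,
        universe=(0.0, 1.0),
        units="boolean",
        labels=(
            MembershipFunction(
                label="No", shape=MFShape.crisp_singleton, breakpoints=(0.0,)
            ),
            MembershipFunction(
                label="Yes", shape=MFShape.crisp_singleton, breakpoints=(1.0,)
            ),
        ),
    )


def default_fis4h() -> FISConfig:
    """Help controller: per-second help activation / step cancellation.

    Inputs: windowed stress percentage, seconds without a correct
    selection, and consecutive errors since the last correct selection.
    Output: keep the help as it is, activate it, or cancel the step.
    """
    output = LinguisticVariable(
        name="help_action",
        universe=(0.0, 100.0),
        units="action index",
        labels=(
            _trap(HELP_DO_NOT_MODIFY, 0, 0, 20, 40),
            _tri(HELP_ACTIVATE, 30, 50, 70),
            _trap(HELP_CANCEL, 60, 80, 100, 100),
        ),
    )
    rules = (
        FuzzyRule(
            antecedents={
                "current_stress": "Low",
                "time_without_interaction": ANY,
                "consecutive_errors": ANY,
            },
            consequent=HELP_DO_NOT_MODIFY,
        ),
        FuzzyRule(
            antecedents={
                "current_stress": ANY,
                "time_without_interaction": "Low",
                "consecutive_errors": "Low",
            },
            consequent=HELP_DO_NOT_MODIFY,
        ),
        FuzzyRule(
            antecedents={
                "current_stress": "High",
                "time_without_interaction": "Medium",
                "consecutive_errors": "Medium",
            },
            consequent=HELP_ACTIVATE,
        ),
        FuzzyRule(
            antecedents={
                "current_stress": ANY,
                "time_without_interaction": "High",
                "consecutive_errors": "Medium",
            },
            consequent=HELP_ACTIVATE,
        ),
        FuzzyRule(
            antecedents={
                "current_stress": "High",
                "time_without_interaction": "High",
                "consecutive_errors": "High",
            },
            consequent=HELP_CANCEL,
        ),
    )
    return FISConfig(
        name="FIS4H",
        inputs=(
            three_label_partition("current_stress", 0.0, 100.0, "%"),
            three_label_partition("time_without_interaction", 0.0, 60.0, "s"),
            three_label_partition("consecutive_errors", 0.0, 10.0, "count"),
        ),
        output=output,
        rules=rules,
        default_output_label=HELP_DO_NOT_MODIFY,
        # conservative-action preference on exact ties
        tie_break=(HELP_DO_NOT_MODIFY, HELP_ACTIVATE, HELP_CANCEL),
    )


def default_fis4d() -> FISConfig:
    """Difficulty controller: between-step offset of the next step's level.

    Inputs: average windowed stress over the last quarter of the step,
    the step's errors ratio, and whether the step was canceled.  The
    extreme output labels are shoulder trapezoids so that a canceled
    step (rule 5 at full strength) still decodes to the strong decrease
    even when the moderate-decrease rule fires alongside it.
    """
    output = LinguisticVariable(
        name="difficulty_offset",
        universe=(0.0, 100.0),
        units="offset index",
        labels=(
            _trap(D_MINUS_MINUS, 0, 0, 10, 25),
            _tri(D_MINUS, 15, 30, 45),
            _tri(D_EQUAL, 40, 50, 60),
            _tri(D_PLUS, 55, 70, 85),
            _trap(D_PLUS_PLUS, 75, 90, 100, 100),
        ),
    )
    rules = (
        FuzzyRule(
            antecedents={
                "step_average_stress": ANY,
                "step_errors_ratio": "Low",
                "step_canceled": ANY,
            },
            consequent=D_PLUS_PLUS,
        ),
        FuzzyRule(
            antecedents={
                "step_average_stress": "Low",
                "step_errors_ratio": ANY,
                "step_canceled": ANY,
            },
            consequent=D_PLUS,
        ),
        FuzzyRule(
            antecedents={
                "step_average_stress": "Medium",
                "step_errors_ratio": "Medium",
                "step_canceled": ANY,
            },
            consequent=D_EQUAL,
        ),
        FuzzyRule(
            antecedents={
                "step_average_stress": ANY,
                "step_errors_ratio": "High",
                "step_canceled": ANY,
            },
            consequent=D_MINUS,
        ),
        FuzzyRule(
            antecedents={
                "step_average_stress": ANY,
                "step_errors_ratio": ANY,
                "step_canceled": "Yes",
            },
            consequent=D_MINUS_MINUS,
        ),
    )
    return FISConfig(
        name="FIS4D",
        inputs=(
            three_label_partition("step_average_stress", 0.0, 100.0, "%"),
            three_label_partition("step_errors_ratio", 0.0, 1.0, "ratio"),
            yes_no_variable("step_canceled"),
        ),
        output=output,
        rules=rules,
        default_output_label=D_EQUAL,
        # smaller |offset| first, negative before positive on exact ties
        tie_break=(D_EQUAL, D_MINUS, D_PLUS, D_MINUS_MINUS, D_PLUS_PLUS),
    )


def default_profile(name: str = "default") -> RuleProfile:
    """The shipped profile: default partitions, example rule bases, 10 s window."""
    return RuleProfile(
        name=name,
        fis4h=default_fis4h(),
        fis4d=default_fis4d(),
        signal=SignalConfig(),
    )
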