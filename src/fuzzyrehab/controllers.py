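"""Domain wrappers around the two fuzzy systems.

The help controller runs once per tick during a step and can only ever
turn help *on* or request cancellation of the step; help turns off
exclusively when the patient makes a correct selection (latching).  The
difficulty controller runs once per completed step and yields an integer
offset in {-2..+2} that is applied to the next step's base level and
clamped to that step's valid range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .errors import ConfigurationError
from .fuzzy import FISConfig, infer
from .profiles import OFFSET_BY_LABEL
from .signals import StepSummary


class HelpAction(str, Enum):
    DO_NOT_MODIFY = "do_not_modify"
    ACTIVATE_HELP = "activate_help"
    CANCEL_STEP = "cancel_step"


class HelpType(str, Enum):
    """Which assistance modality the exercise is configured to use."""

    VISUAL = "visual"
    HAPTIC = "haptic"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class HelpState:
    """Latched assistance flags; starts deactivated at every step start."""

    visual_active: bool = False
    haptic_active: bool = False
    help_type: HelpType = HelpType.BOTH

    @property
    def any_active(self) -> bool:
        return self.visual_active or self.haptic_active


def evaluate_help(
    fis4h: FISConfig,
    current_stress: float | None,
    time_without_interaction: float,
    consecutive_errors: int,
) -> HelpAction:
    """One per-tick evaluation of the help controller.

    A ``None`` stress value (warm-up, before the first headset reading)
    is treated as 0.
    """
    result = infer(
        fis4h,
        {
            "current_stress": 0.0 if current_stress is None else current_stress,
            "time_without_interaction": time_without_interaction,
            "consecutive_errors": float(consecutive_errors),
        },
    )
    try:
        return HelpAction(result.label)
    except ValueError:
        raise ConfigurationError(
            f"FIS4H output label {result.label!r} is not a help action"
        ) from None


def apply_help_action(
    state: HelpState, action: HelpAction
) -> tuple[HelpState, bool]:
    """Apply a controller output; returns (new state, cancel_requested).

    Activation turns on the configured modalities (a no-op when already
    active); the controller can never deactivate help; cancellation does
    not touch the help flags.
    """
    if action is HelpAction.CANCEL_STEP:
        return state, True
    if action is HelpAction.ACTIVATE_HELP:
        return (
            replace(
                state,
                visual_active=state.visual_active
                or state.help_type in (HelpType.VISUAL, HelpType.BOTH),
                haptic_active=state.haptic_active
                or state.help_type in (HelpType.HAPTIC, HelpType.BOTH),
            ),
            False,
        )
    return state, False


def on_hit(state: HelpState) -> HelpState:
    """A correct selection releases the latch: all help flags off."""
    return replace(state, visual_active=False, haptic_active=False)


def evaluate_difficulty(fis4d: FISConfig, summary: StepSummary) -> int:
    """Between-step evaluation: decode the selected label to an offset.

    The canceled flag enters the FIS as a crisp 0/1 singleton input.
    """
    result = infer(
        fis4d,
        {
            "step_average_stress": summary.step_average_stress,
            "step_errors_ratio": summary.step_errors_ratio,
            "step_canceled": 1.0 if summary.step_canceled else 0.0,
        },
    )
    try:
        return OFFSET_BY_LABEL[result.label]
    except KeyError:
        raise ConfigurationError(
            f"FIS4D output label {result.label!r} has no offset semantics"
        ) from None


def next_level(base_level: int, offset: int, n_levels: int) -> int:
    """Apply an offset to a 1-based level index, clamping to [1, n_levels]."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if not 1 <= base_level <= n_levels:
        raise ValueError(
            f"base_level {base_level} outside [1, {n_levels}]"
        )
    return min(max(base_level + offset, 1), n_levels)
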