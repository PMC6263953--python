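"""Input features for the two controllers.

The headset emits one stress reading per second as a decimal in [0, 1].
Rather than feeding that raw signal to the help controller, each reading
is classified against a threshold and the controller sees the percentage
of high-stress samples over a short sliding window, so a single spike or
a false reading cannot steer the exercise.  Between steps, the
difficulty controller sees the mean of that windowed percentage over the
trailing fraction of the step together with the step's errors ratio.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

log = logging.getLogger(__name__)


class SignalConfig(BaseModel):
    """Parameters of the stress/interaction feature pipeline.

    window_size
        Number of 1 Hz headset readings in the sliding window (default 10,
        i.e. the last 10 s).
    stress_threshold
        Cutoff on the raw reading; a sample at or above it counts as high.
    avg_fraction
        Trailing fraction of the step over which the windowed stress
        percentage is averaged for the difficulty controller (default the
        last quarter).
    tick_interval
        Seconds between samples.
    """

    model_config = ConfigDict(frozen=True)

    window_size: int = Field(default=10, ge=1)
    stress_threshold: float = Field(default=0.5, gt=0.0, lt=1.0)
    avg_fraction: float = Field(default=0.25, gt=0.0, le=1.0)
    tick_interval: float = Field(default=1.0, gt=0.0)


class Event(str, Enum):
    """Patient interaction outcomes observed on one tick."""

    HIT = "hit"
    COGNITIVE_ERROR = "cognitive_error"
    DISTRACTOR_ERROR = "distractor_error"
    IDLE = "idle"


#: Event kinds that count as errors in the step errors ratio.
ERROR_EVENTS = (Event.COGNITIVE_ERROR, Event.DISTRACTOR_ERROR)


def classify_sample(reading: float, threshold: float) -> bool:
    """True when the reading counts as a high-stress sample (>= threshold).

    Readings outside [0, 1] are clamped with a warning; the loop must
    survive sensor glitches.
    """
    if not 0.0 <= reading <= 1.0:
        log.warning("stress reading %.4g outside [0, 1]; clamping", reading)
        reading = min(max(reading, 0.0), 1.0)
    return reading >= threshold


class StressWindow:
    """Bounded FIFO of the most recent headset readings."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("window capacity must be >= 1")
        self._readings: deque[float] = deque(maxlen=capacity)

    def push(self, reading: float) -> None:
        if not 0.0 <= reading <= 1.0:
            log.warning("stress reading %.4g outside [0, 1]; clamping", reading)
            reading = min(max(reading, 0.0), 1.0)
        self._readings.append(reading)

    def clear(self) -> None:
        self._readings.clear()

    def __len__(self) -> int:
        return len(self._readings)

    @property
    def readings(self) -> tuple[float, ...]:
        return tuple(self._readings)


def current_stress(
    window: StressWindow | Sequence[float], cfg: SignalConfig
) -> Optional[float]:
    """Windowed stress percentage: 100 × high samples / total samples.

    Uses however many readings are present (the loop runs from the first
    second, before the window has filled).  Returns ``None`` for an empty
    window.
    """
    readings = window.readings if isinstance(window, StressWindow) else tuple(window)
    if not readings:
        return None
    n_high = sum(classify_sample(r, cfg.stress_threshold) for r in readings)
    return 100.0 * n_high / len(readings)


def step_average_stress(
    series: Sequence[float], fraction: float
) -> Optional[float]:
    """Mean of the trailing ``ceil(fraction × len)`` values of the series.

    ``series`` is the per-second windowed stress percentage over one step.
    Returns ``None`` for an empty series.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not series:
        return None
    k = max(1, math.ceil(fraction * len(series)))
    tail = series[len(series) - k :]
    return float(sum(tail)) / len(tail)


def step_errors_ratio(errors: int, hits: int) -> float:
    """errors / (errors + hits), with 0/0 defined as 0."""
    if errors < 0 or hits < 0:
        raise ValueError("error and hit counts must be non-negative")
    total = errors + hits
    return errors / total if total else 0.0


@dataclass(frozen=True)
class InteractionState:
    """Per-step counters driving the help controller.

    Both reset to zero on a correct selection; the clock also runs from
    step start.
    """

    time_without_interaction: float = 0.0
    consecutive_errors: int = 0


def update_interaction(
    state: InteractionState, event: Event, dt: float
) -> InteractionState:
    """Advance the counters by one observed tick.

    A hit resets both; an error increments the error count while the
    clock keeps running; idle only advances the clock.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if event is Event.HIT:
        return InteractionState(0.0, 0)
    if event in ERROR_EVENTS:
        return InteractionState(
            state.time_without_interaction + dt, state.consecutive_errors + 1
        )
    if event is Event.IDLE:
        return InteractionState(
            state.time_without_interaction + dt, state.consecutive_errors
        )
    raise ValueError(f"unknown event kind: {event!r}")


class StepSummary(BaseModel):
    """What the difficulty controller sees about a finished step."""

    model_config = ConfigDict(frozen=True)

    step_average_stress: float = Field(ge=0.0, le=100.0)
    step_errors_ratio: float = Field(ge=0.0, le=1.0)
    step_canceled: bool
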