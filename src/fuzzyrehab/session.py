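"""Exercise execution: data model, per-second control loop, progression.

An exercise is an ordered list of steps; each step carries nested
difficulty levels (every level contains all elements of the level below
it, unchanged) and a therapist-chosen base level.  During a step the
help controller runs once per tick; when the step ends the difficulty
controller emits an offset that shifts the *next* step's base level,
clamped to its valid range.  The offset emitted after the final step is
carried over to the first step of the next execution, and interrupted
sessions resume at the interrupted step.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Protocol, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .controllers import (
    HelpAction,
    HelpState,
    HelpType,
    apply_help_action,
    evaluate_difficulty,
    evaluate_help,
    next_level,
    on_hit,
)
from .errors import PatientSourceExhausted, StateError
from .profiles import RuleProfile
from .signals import (
    ERROR_EVENTS,
    Event,
    InteractionState,
    StepSummary,
    StressWindow,
    current_stress,
    step_average_stress,
    step_errors_ratio,
    update_interaction,
)

FORMAT_VERSION = "1.0"


# --- Exercise data model -------------------------------------------------


class ElementDef(BaseModel):
    """One on-screen element: a target to select or a distractor to avoid."""

    model_config = ConfigDict(frozen=True)

    id: str
    kind: Literal["target", "distractor"]
    position: tuple[float, float] = (0.5, 0.5)  # screen fractions, origin top-left
    sequence: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "ElementDef":
        x, y = self.position
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise ValueError(f"element {self.id!r} position outside the screen")
        return self


class DifficultyLevelDef(BaseModel):
    model_config = ConfigDict(frozen=True)

    index: int = Field(ge=1)
    elements: tuple[ElementDef, ...]

    @model_validator(mode="after")
    def _check(self) -> "DifficultyLevelDef":
        ids = [e.id for e in self.elements]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate element ids in level {self.index}")
        return self

    @property
    def targets(self) -> tuple[ElementDef, ...]:
        return tuple(e for e in self.elements if e.kind == "target")

    @property
    def n_distractors(self) -> int:
        return sum(1 for e in self.elements if e.kind == "distractor")


class StepDef(BaseModel):
    model_config = ConfigDict(frozen=True)

    index: int = Field(ge=1)
    levels: tuple[DifficultyLevelDef, ...]
    base_level: int = Field(ge=1)

    @model_validator(mode="after")
    def _check(self) -> "StepDef":
        if not self.levels:
            raise ValueError(f"step {self.index} has no levels")
        for want, lvl in enumerate(self.levels, start=1):
            if lvl.index != want:
                raise ValueError(
                    f"step {self.index}: level indices must be 1..n in order"
                )
        if self.base_level > len(self.levels):
            raise ValueError(
                f"step {self.index}: base_level {self.base_level} exceeds "
                f"{len(self.levels)} levels"
            )
        # incremental-difficulty invariant: each level extends the one below
        for lower, upper in zip(self.levels, self.levels[1:]):
            upper_by_id = {e.id: e for e in upper.elements}
            for e in lower.elements:
                if e.id not in upper_by_id:
                    raise ValueError(
                        f"step {self.index}: level {upper.index} is missing "
                        f"element {e.id!r} of level {lower.index}"
                    )
                if upper_by_id[e.id] != e:
                    raise ValueError(
                        f"step {self.index}: level {upper.index} modifies "
                        f"element {e.id!r} of level {lower.index}"
                    )
        return self

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level(self, index: int) -> DifficultyLevelDef:
        if not 1 <= index <= self.n_levels:
            raise ValueError(
                f"step {self.index} has no level {index} (1..{self.n_levels})"
            )
        return self.levels[index - 1]


class ExerciseOptions(BaseModel):
    """Session-wide options mirroring the exercise editor's option block."""

    model_config = ConfigDict(frozen=True)

    repetitions: int = Field(default=1, ge=1)
    help_type: HelpType = HelpType.BOTH
    max_exercise_time: float = Field(default=0.0, ge=0.0)  # 0 = unlimited
    cognitive_lives: int = Field(default=0, ge=0)  # 0 = unlimited
    distractor_lives: int = Field(default=0, ge=0)
    initial_explanation: str = ""
    initial_explanation_time: float = Field(default=0.0, ge=0.0)
    hit_points: int = Field(default=10, ge=0)
    error_points: int = Field(default=5, ge=0)


class ExerciseDef(BaseModel):
    model_config = ConfigDict(frozen=True)

    format_version: str = FORMAT_VERSION
    id: str
    steps: tuple[StepDef, ...]
    options: ExerciseOptions = ExerciseOptions()

    @model_validator(mode="after")
    def _check(self) -> "ExerciseDef":
        if not self.steps:
            raise ValueError("an exercise needs at least one step")
        for want, step in enumerate(self.steps, start=1):
            if step.index != want:
                raise ValueError("step indices must be 1..n in order")
        return self

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def step(self, index: int) -> StepDef:
        if not 1 <= index <= self.n_steps:
            raise StateError(f"exercise has no step {index}")
        return self.steps[index - 1]


# --- Telemetry -----------------------------------------------------------


class TelemetrySample(BaseModel):
    """One 1 Hz log record taken during a step."""

    model_config = ConfigDict(frozen=True)

    timestamp: float  # seconds from step start
    percent_completed: float
    activated_elements: int
    cognitive_errors: int
    distractor_errors: int
    elapsed_time: float
    current_stress: float
    time_without_interaction: float
    consecutive_errors: int
    score: int
    visual_help: bool
    haptic_help: bool
    screenshot: None = None  # captured by the client, never by this engine


StepStatus = Literal["completed", "canceled", "interrupted"]


class StepRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    step_index: int
    level_played: int
    status: StepStatus
    samples: tuple[TelemetrySample, ...]
    summary: StepSummary
    offset: int = Field(ge=-2, le=2)


class SessionRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    format_version: str = FORMAT_VERSION
    exercise_id: str
    options: ExerciseOptions
    steps: tuple[StepRecord, ...]
    final_score: int
    completion_status: Literal["complete", "incomplete"]


# --- Progress / carryover ------------------------------------------------


class ProgressState(BaseModel):
    """Cross-session memory: adjusted base levels and the resume point."""

    model_config = ConfigDict(frozen=True)

    base_levels: tuple[int, ...]
    resume_index: int = 1  # 1-based index of the next step to perform
    last_offset: int = 0  # offset emitted by the most recent completed step
    pending_first_offset: int = 0  # final offset awaiting the next execution
    exercise_complete: bool = False
    start_level_override: Optional[int] = None  # mid-step interruption resume
    sessions_played: int = 0


def initial_progress(exercise: ExerciseDef) -> ProgressState:
    return ProgressState(
        base_levels=tuple(s.base_level for s in exercise.steps)
    )


def complete_step(
    progress: ProgressState,
    exercise: ExerciseDef,
    step_index: int,
    summary: StepSummary,
    offset: int,
) -> ProgressState:
    """Advance the resume point after a step and stash its offset.

    The offset of a non-final step shifts the starting level of the next
    step in this session; the final step's offset is stored as the
    pending adjustment of the first step's base for the next execution.
    """
    if progress.exercise_complete or step_index != progress.resume_index:
        raise StateError(
            f"step {step_index} completed out of order (resume point is "
            f"{progress.resume_index})"
        )
    if step_index == exercise.n_steps:
        return progress.model_copy(
            update=dict(
                resume_index=1,
                last_offset=0,
                pending_first_offset=offset,
                exercise_complete=True,
                start_level_override=None,
            )
        )
    return progress.model_copy(
        update=dict(
            resume_index=step_index + 1,
            last_offset=offset,
            start_level_override=None,
        )
    )


def carry_over(
    progress: ProgressState, last: SessionRecord, exercise: ExerciseDef
) -> ProgressState:
    """Fold one finished session into the progress for the next one.

    After a complete session the first step's base shifts by the final
    offset and every other attempted step's base becomes the level that
    was actually played; after an incomplete session the resume point is
    the interrupted step, which restarts at the level it was being
    played at.
    """
    if last.exercise_id != exercise.id:
        raise StateError(
            f"session record belongs to exercise {last.exercise_id!r}, "
            f"not {exercise.id!r}"
        )
    played = {rec.step_index: rec for rec in last.steps}
    bases = list(progress.base_levels)
    for i in range(2, exercise.n_steps + 1):
        if i in played:
            bases[i - 1] = played[i].level_played
    override: Optional[int] = None
    if last.completion_status == "complete":
        bases[0] = next_level(
            bases[0], progress.pending_first_offset, exercise.step(1).n_levels
        )
        resume = 1
    else:
        interrupted = [r for r in last.steps if r.status == "interrupted"]
        if interrupted:
            resume = interrupted[-1].step_index
            override = interrupted[-1].level_played
        else:
            resume = min(max(played, default=0) + 1, exercise.n_steps)
        if resume == 1 and 1 in played:
            bases[0] = played[1].level_played
    return ProgressState(
        base_levels=tuple(bases),
        resume_index=resume,
        last_offset=0,
        pending_first_offset=0,
        exercise_complete=False,
        start_level_override=override,
        sessions_played=progress.sessions_played + 1,
    )


# --- Scoring -------------------------------------------------------------


def update_score(
    score: int, event: Event, hit_points: int = 10, error_points: int = 5
) -> int:
    """Hits add points, errors subtract them, the score never goes negative."""
    if event is Event.HIT:
        return score + hit_points
    if event in ERROR_EVENTS:
        return max(0, score - error_points)
    return score


# --- Patient source protocol ---------------------------------------------


class PatientSource(Protocol):
    """Anything that can stand in for the patient + headset during a step."""

    def begin_step(
        self, step_index: int, level: int, n_levels: int,
        n_targets: int, n_distractors: int,
    ) -> None:
        """Called once when a step starts (lets stateful models reset)."""

    def stress_reading(self) -> float:
        """One raw headset reading in [0, 1] for the current tick."""

    def next_event(
        self, remaining_targets: int, n_distractors: int, help_active: bool
    ) -> Event:
        """The patient's interaction outcome for the current tick."""


# --- Per-step control loop -----------------------------------------------


def run_step(
    step: StepDef,
    level: int,
    patient: PatientSource,
    profile: RuleProfile,
    options: ExerciseOptions = ExerciseOptions(),
    *,
    step_index: Optional[int] = None,
    initial_score: int = 0,
    time_budget: Optional[float] = None,
    max_ticks: Optional[int] = None,
) -> tuple[StepRecord, int]:
    """Execute one step tick by tick until it terminates.

    Per tick: ingest the stress reading into the sliding window, ingest
    the interaction event (updating counters, score, lives and the
    activation set), evaluate the help controller and apply its action,
    then emit one telemetry sample.  The step ends when every target of
    the level is activated, when the controller requests cancellation,
    when lives run out, or when the time budget expires (recorded as an
    interruption).  Returns the step record and the running score.
    """
    cfg = profile.signal
    lvl = step.level(level)
    n_targets = len(lvl.targets)
    n_distractors = lvl.n_distractors
    idx = step_index if step_index is not None else step.index
    patient.begin_step(idx, level, step.n_levels, n_targets, n_distractors)

    window = StressWindow(cfg.window_size)
    inter = InteractionState()
    help_state = HelpState(help_type=options.help_type)
    score = initial_score
    activated = cog_err = dis_err = hits = 0
    cognitive_left = options.cognitive_lives or None
    distractor_left = options.distractor_lives or None
    stress_series: list[float] = []
    samples: list[TelemetrySample] = []
    status: Optional[StepStatus] = None
    t = 0.0
    tick = 0

    while status is None:
        tick += 1
        t += cfg.tick_interval
        try:
            reading = patient.stress_reading()
            window.push(reading)
            remaining = n_targets - activated
            event = patient.next_event(
                remaining, n_distractors, help_state.any_active
            )
        except StopIteration:
            raise PatientSourceExhausted(
                f"patient source exhausted at tick {tick} of step {idx}"
            ) from None
        cs = current_stress(window, cfg)
        assert cs is not None  # a reading was just pushed
        inter = update_interaction(inter, event, cfg.tick_interval)
        score = update_score(
            score, event, options.hit_points, options.error_points
        )
        if event is Event.HIT:
            hits += 1
            if activated < n_targets:
                activated += 1
            help_state = on_hit(help_state)
        elif event is Event.COGNITIVE_ERROR:
            cog_err += 1
            if cognitive_left is not None:
                cognitive_left -= 1
        elif event is Event.DISTRACTOR_ERROR:
            dis_err += 1
            if distractor_left is not None:
                distractor_left -= 1

        action = evaluate_help(
            profile.fis4h,
            cs,
            inter.time_without_interaction,
            inter.consecutive_errors,
        )
        help_state, cancel_requested = apply_help_action(help_state, action)
        stress_series.append(cs)
        samples.append(
            TelemetrySample(
                timestamp=t,
                percent_completed=100.0 * activated / n_targets
                if n_targets
                else 100.0,
                activated_elements=activated,
                cognitive_errors=cog_err,
                distractor_errors=dis_err,
                elapsed_time=t,
                current_stress=cs,
                time_without_interaction=inter.time_without_interaction,
                consecutive_errors=inter.consecutive_errors,
                score=score,
                visual_help=help_state.visual_active,
                haptic_help=help_state.haptic_active,
            )
        )

        if activated >= n_targets:
            status = "completed"
        elif cancel_requested:
            status = "canceled"
        elif (cognitive_left is not None and cognitive_left <= 0) or (
            distractor_left is not None and distractor_left <= 0
        ):
            status = "canceled"
        elif time_budget is not None and t >= time_budget:
            status = "interrupted"
        elif max_ticks is not None and tick >= max_ticks:
            status = "interrupted"

    avg = step_average_stress(stress_series, cfg.avg_fraction)
    summary = StepSummary(
        step_average_stress=avg if avg is not None else 0.0,
        step_errors_ratio=step_errors_ratio(cog_err + dis_err, hits),
        step_canceled=status != "completed",
    )
    record = StepRecord(
        step_index=idx,
        level_played=level,
        status=status,
        samples=tuple(samples),
        summary=summary,
        offset=0,  # filled in by the session loop after FIS4D runs
    )
    return record, score


def summarize_samples(
    samples: Sequence[TelemetrySample],
    status: StepStatus,
    avg_fraction: float = 0.25,
) -> StepSummary:
    """Recompute a StepSummary from a telemetry trace (replay path).

    Hits equal the final count of activated elements; errors are the
    final cognitive + distractor counts; the canceled flag mirrors the
    recorded step status.
    """
    if not samples:
        raise ValueError("cannot summarize an empty sample trace")
    series = [s.current_stress for s in samples]
    last = samples[-1]
    avg = step_average_stress(series, avg_fraction)
    return StepSummary(
        step_average_stress=avg if avg is not None else 0.0,
        step_errors_ratio=step_errors_ratio(
            last.cognitive_errors + last.distractor_errors,
            last.activated_elements,
        ),
        step_canceled=status != "completed",
    )


# --- Session loop --------------------------------------------------------


def run_session(
    exercise: ExerciseDef,
    progress: ProgressState,
    patient: PatientSource,
    profile: RuleProfile,
) -> tuple[SessionRecord, ProgressState]:
    """Play the exercise from the resume point through the last step.

    Between steps the difficulty controller converts the step summary
    into an offset; the next step starts at its base level shifted by
    that offset and clamped to its range.  The whole-exercise time limit
    (``max_exercise_time``, 0 = unlimited) interrupts the current step
    and ends the session incomplete.
    """
    if progress.exercise_complete:
        raise StateError("progress is marked complete; run carry_over first")
    if len(progress.base_levels) != exercise.n_steps:
        raise StateError("progress does not match the exercise's step count")
    options = exercise.options
    total_budget = options.max_exercise_time or None
    elapsed = 0.0
    score = 0
    records: list[StepRecord] = []
    idx = progress.resume_index
    first_of_session = True

    while idx <= exercise.n_steps:
        step = exercise.step(idx)
        if first_of_session and progress.start_level_override is not None:
            level = progress.start_level_override
        elif first_of_session or idx == 1:
            level = progress.base_levels[idx - 1]
        else:
            level = next_level(
                progress.base_levels[idx - 1],
                progress.last_offset,
                step.n_levels,
            )
        first_of_session = False
        budget = None if total_budget is None else total_budget - elapsed
        record, score = run_step(
            step,
            level,
            patient,
            profile,
            options,
            initial_score=score,
            time_budget=budget,
        )
        elapsed += record.samples[-1].timestamp if record.samples else 0.0
        if record.status == "interrupted":
            records.append(record)
            new_progress = progress.model_copy(
                update=dict(
                    resume_index=idx,
                    start_level_override=level,
                    last_offset=0,
                )
            )
            session = SessionRecord(
                exercise_id=exercise.id,
                options=options,
                steps=tuple(records),
                final_score=score,
                completion_status="incomplete",
            )
            return session, new_progress
        offset = evaluate_difficulty(profile.fis4d, record.summary)
        record = record.model_copy(update=dict(offset=offset))
        records.append(record)
        progress = complete_step(progress, exercise, idx, record.summary, offset)
        idx += 1

    session = SessionRecord(
        exercise_id=exercise.id,
        options=options,
        steps=tuple(records),
        final_score=score,
        completion_status="complete",
    )
    return session, progress


# --- Synthetic exercise builders ----------------------------------------


def _grid_position(i: int) -> tuple[float, float]:
    return (0.1 + 0.2 * (i % 5), 0.1 + 0.2 * ((i // 5) % 5))


def make_level(index: int, n_targets: int, n_distractors: int) -> DifficultyLevelDef:
    elements = [
        ElementDef(
            id=f"t{i + 1}", kind="target", position=_grid_position(i),
            sequence=i + 1,
        )
        for i in range(n_targets)
    ] + [
        ElementDef(
            id=f"d{i + 1}", kind="distractor", position=_grid_position(10 + i)
        )
        for i in range(n_distractors)
    ]
    return DifficultyLevelDef(index=index, elements=tuple(elements))


def make_step(
    index: int, n_levels: int, base_level: int, targets_at_base: int = 3
) -> StepDef:
    """Nested levels: level k has k+offset targets and k//2 distractors."""
    start = max(1, targets_at_base - base_level + 1)
    levels = tuple(
        make_level(k, start + (k - 1), (k - 1) // 2) for k in range(1, n_levels + 1)
    )
    return StepDef(index=index, levels=levels, base_level=base_level)


def make_demo_exercise(options: Optional[ExerciseOptions] = None) -> ExerciseDef:
    """Six-step demo exercise with the documented level/base layout.

    Step 1 has seven levels with base 4 and step 2 has four levels with
    base 2; the remaining steps are shaped so that the full worked
    progression (+1, −2, −1, −2, 0, +2 → levels 3, 1, 4, 1, base, and a
    next-execution start of 6) is expressible.
    """
    shape = [(7, 4), (4, 2), (5, 3), (6, 5), (3, 2), (5, 3)]
    steps = tuple(
        make_step(i + 1, n_levels, base)
        for i, (n_levels, base) in enumerate(shape)
    )
    return ExerciseDef(
        id="demo-6-step",
        steps=steps,
        options=options or ExerciseOptions(),
    )
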