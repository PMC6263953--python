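"""Stochastic patient model closing the control loop without hardware.

The simulator emulates two streams the real system gets from sensors and
the touch surface: a 1 Hz stress reading in [0, 1] (first-order
autoregressive pull toward a baseline raised by difficulty pressure,
plus bounded uniform noise) and one interaction event per tick (hit,
cognitive error, distractor error or idle, with the hit probability
scaled up while help is active).  Archetype presets exist so cohort
studies can contrast proficient, average and struggling behavior; the
parameters are engineering knobs chosen to exercise every controller
output, not claims about clinical populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .signals import Event


class PatientProfile(BaseModel):
    """Behavioral parameters of one simulated patient."""

    model_config = ConfigDict(frozen=True)

    skill: float = Field(ge=0.0, le=1.0)
    stress_baseline: float = Field(ge=0.0, le=1.0)
    stress_reactivity: float = Field(default=0.1, ge=0.0)
    stress_persistence: float = Field(default=0.8, ge=0.0, lt=1.0)
    help_benefit: float = Field(default=1.5, ge=1.0)
    distractor_susceptibility: float = Field(default=0.1, ge=0.0, le=1.0)
    idle_share: float = Field(default=0.5, ge=0.0, le=1.0)
    noise_amplitude: float = Field(default=0.05, ge=0.0, le=0.5)
    seed: int = 0


@dataclass
class PatientState:
    """Latent per-step state of the simulator."""

    stress: float = 0.0
    fatigue: float = 0.0


def stress_sample(
    state: PatientState,
    profile: PatientProfile,
    difficulty_pressure: float,
    rng: np.random.Generator,
) -> float:
    """Advance the latent stress one tick and emit a reading in [0, 1].

    The latent level relaxes toward ``baseline + reactivity × pressure``
    with autoregressive coefficient ``stress_persistence``; uniform
    noise of amplitude ``noise_amplitude`` is added and the result is
    clamped.
    """
    if difficulty_pressure < 0:
        raise ValueError("difficulty_pressure must be >= 0")
    target = profile.stress_baseline + profile.stress_reactivity * difficulty_pressure
    target = min(max(target, 0.0), 1.0)
    p = profile.stress_persistence
    state.stress = p * state.stress + (1.0 - p) * target
    noise = (
        rng.uniform(-profile.noise_amplitude, profile.noise_amplitude)
        if profile.noise_amplitude > 0
        else 0.0
    )
    reading = min(max(state.stress + noise, 0.0), 1.0)
    return reading


def next_event(
    state: PatientState,
    profile: PatientProfile,
    remaining_targets: int,
    n_distractors: int,
    help_active: bool,
    rng: np.random.Generator,
) -> Event:
    """Draw the interaction outcome for one tick.

    A hit occurs with probability ``min(1, skill × help_benefit)`` when
    help is active (plain skill otherwise); failing that, a distractor
    error occurs with probability ``distractor_susceptibility`` when
    distractors are on screen; the remainder splits between idling and
    cognitive errors by ``idle_share``.
    """
    p_hit = min(1.0, profile.skill * (profile.help_benefit if help_active else 1.0))
    if remaining_targets > 0 and rng.random() < p_hit:
        return Event.HIT
    if n_distractors > 0 and rng.random() < profile.distractor_susceptibility:
        return Event.DISTRACTOR_ERROR
    return Event.IDLE if rng.random() < profile.idle_share else Event.COGNITIVE_ERROR


def comfortable_level(profile: PatientProfile, n_levels: int) -> int:
    """Skill-implied level the patient handles without added stress."""
    return 1 + math.floor(profile.skill * (n_levels - 1))


class SimulatedPatient:
    """PatientSource adapter wiring the stochastic model into the engine.

    One shared pseudo-random stream drives both the stress and the event
    draws, so a (profile, seed) pair fully determines a session.
    """

    def __init__(self, profile: PatientProfile, seed: Optional[int] = None):
        self.profile = profile
        self.rng = np.random.default_rng(
            profile.seed if seed is None else seed
        )
        self.state = PatientState(stress=profile.stress_baseline)
        self._pressure = 0.0

    def begin_step(
        self, step_index: int, level: int, n_levels: int,
        n_targets: int, n_distractors: int,
    ) -> None:
        self._pressure = float(
            max(0, level - comfortable_level(self.profile, n_levels))
        )

    def stress_reading(self) -> float:
        return stress_sample(self.state, self.profile, self._pressure, self.rng)

    def next_event(
        self, remaining_targets: int, n_distractors: int, help_active: bool
    ) -> Event:
        return next_event(
            self.state,
            self.profile,
            remaining_targets,
            n_distractors,
            help_active,
            self.rng,
        )


class ScriptedPatient:
    """Deterministic PatientSource replaying fixed stress/event traces.

    Raises ``StopIteration`` (reported by the engine as an exhausted
    source) when a trace runs dry.
    """

    def __init__(self, stress: Iterable[float], events: Iterable[Event]):
        self._stress = iter(stress)
        self._events = iter(events)

    def begin_step(self, *args: int) -> None:  # noqa: D102 - stateless
        pass

    def stress_reading(self) -> float:
        return next(self._stress)

    def next_event(
        self, remaining_targets: int, n_distractors: int, help_active: bool
    ) -> Event:
        return next(self._events)


#: Archetype presets: (skill, baseline, reactivity, persistence,
#: help_benefit, distractor_susceptibility, idle_share).
ARCHETYPES: dict[str, dict[str, float]] = {
    "proficient": dict(
        skill=0.60, stress_baseline=0.15, stress_reactivity=0.05,
        stress_persistence=0.80, help_benefit=1.3,
        distractor_susceptibility=0.05, idle_share=0.6,
    ),
    "average": dict(
        skill=0.30, stress_baseline=0.35, stress_reactivity=0.10,
        stress_persistence=0.80, help_benefit=1.4,
        distractor_susceptibility=0.15, idle_share=0.5,
    ),
    "struggling": dict(
        skill=0.05, stress_baseline=0.58, stress_reactivity=0.15,
        stress_persistence=0.85, help_benefit=1.4,
        distractor_susceptibility=0.10, idle_share=0.8,
    ),
}


def make_cohort(archetype: str, n: int, seed: int) -> list[PatientProfile]:
    """Seeded cohort of ``n`` patients jittered around an archetype preset.

    Multiplicative jitter of ±10 % is applied to skill, baseline and
    reactivity (clamped to their valid ranges); each profile gets its
    own derived seed so whole-cohort simulations are reproducible.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(
            f"unknown archetype {archetype!r}; expected one of "
            f"{sorted(ARCHETYPES)}"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    base = ARCHETYPES[archetype]
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        jitter = rng.uniform(0.9, 1.1, size=3)
        cohort.append(
            PatientProfile(
                skill=min(1.0, base["skill"] * jitter[0]),
                stress_baseline=min(1.0, base["stress_baseline"] * jitter[1]),
                stress_reactivity=base["stress_reactivity"] * jitter[2],
                stress_persistence=base["stress_persistence"],
                help_benefit=base["help_benefit"],
                distractor_susceptibility=base["distractor_susceptibility"],
                idle_share=base["idle_share"],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return cohort
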