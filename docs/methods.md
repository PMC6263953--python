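# Methods

This note records the model, the numerical choices, and the places where the
design was genuinely open, so a maintainer can tell deliberate decisions from
accidents.

## The control problem

A cognitive-rehabilitation exercise is an ordered list of *steps*; each step
has nested *difficulty levels* (level k+1 contains every element of level k,
unmodified, plus new targets/distractors) and a therapist-chosen *base level*.
Two controllers supervise execution:

* **FIS4H** (help) runs once per tick (default 1 s, the refresh rate of
  consumer EEG stress metrics). It can activate latched visual/haptic help or
  cancel the step; it can never deactivate help — only a correct selection
  does that. This asymmetry prevents help flicker.
* **FIS4D** (difficulty) runs when a step ends and emits an offset in
  {−2 … +2}. The next step starts at `clamp(base + offset, 1, n_levels)`.
  The final step's offset is remembered and applied to the first step's base
  at the next execution; for every other step, the next execution's base is
  the level actually played. An interrupted session resumes at the
  interrupted step, at the level it was being played.

Both controllers are Mamdani systems: conjunction = min, "Any" antecedents
contribute 1, implication = min (consequents clipped at the rule's firing
strength), aggregation = pointwise max, defuzzification = centroid. OR/NOT
connectives, hedges and Sugeno-style outputs are deliberately out of scope —
the rule bases are small conjunction tables a therapist can read.

## Signal features

The raw stress reading s(t) ∈ [0, 1] is thresholded (s ≥ 0.5 counts as high —
the boundary is inclusive) and summarized as the percentage of high samples in
the last 10 readings. Before the window fills, the denominator is the number
of readings actually present, so the loop is controllable from the first
second. Per step, the difficulty controller sees the mean of that percentage
over the trailing `ceil(0.25 · n)` samples (never fewer than one), and the
errors ratio `errors / (errors + hits)` with 0/0 defined as 0; both cognitive
and distractor errors count as errors.

## Membership geometry (a genuinely open choice)

Rule semantics fix *which* labels exist, not *where* they sit; the shipped
partitions are this package's choice:

* Every graded input uses the same normalized Low/Medium/High pattern —
  Low (0, 0, 20, 45), Medium (30, 50, 70), High (55, 80, 100, 100) on a
  0–100 scale — rescaled to the quantity's natural span: stress percentages
  on [0, 100] %, time-without-interaction on [0, 60] s, consecutive errors on
  [0, 10], errors ratio on [0, 1]. Using natural spans (rather than forcing
  everything onto [0, 100]) keeps the High region of count-like inputs
  reachable in real steps: "high consecutive errors" means ~8 errors, not 80.
  All breakpoints are profile-configurable.
* The canceled flag enters FIS4D as crisp singletons (No = 0, Yes = 1).
* Output universes are [0, 100] with the *extreme* labels as shoulder
  trapezoids and interior labels as triangles. FIS4H: do-not-modify
  (0, 0, 20, 40), activate (30, 50, 70), cancel (60, 80, 100, 100). FIS4D:
  D−− (0, 0, 10, 25), D− (15, 30, 45), D= (40, 50, 60), D+ (55, 70, 85),
  D++ (75, 90, 100, 100).

The shoulder shapes at the ends are load-bearing, not cosmetic. First, they
give full coverage: every point of each universe has positive degree under
some label (pure edge triangles are zero exactly at the endpoints). Second,
they weight the extreme actions enough that a rule firing an extreme
consequent at full strength wins the blend against an adjacent moderate rule:
a canceled step usually also has a High errors ratio, so the D− and D−− rules
fire together, and with equal-area triangles the blended centroid would decode
to D− — defeating the intended "canceled ⇒ strong decrease" semantics. With
the shipped geometry the D−/D−− blend centroid (≈18.8) falls inside the D−−
region (boundary 20), and symmetrically a flawless step (D+/D++ both at full
strength) decodes to +2.

Label selection from the crisp centroid takes the output label with maximal
membership at that value; exact ties resolve toward the more conservative
action (do-not-modify ≻ activate ≻ cancel; smaller |offset| first, then the
negative one). When no rule fires the controllers return their safe defaults
(do-not-modify / keep difficulty).

## Numerics

* The aggregate is sampled on a uniform 1001-point grid (configurable,
  minimum 101). Default-profile breakpoints fall on grid points, so sampling
  the shapes is exact there; clip kinks land between points, contributing a
  sub-0.01 % centroid error.
* The centroid treats the sampled aggregate as the polyline it is: mass by
  the trapezoid rule (exact for a polyline) and first moment by the exact
  per-cell closed form for x·(linear segment), so no integration error is
  added beyond sampling. Zero total mass is reported as a distinguished
  no-activation result, not an exception.
* Out-of-universe crisp inputs are clamped to the nearest endpoint during
  fuzzification (a sensor glitch must not crash the loop); the strict
  `membership_degree` accessor raises instead, for configuration-time checks.
* Determinism: inference is pure; sessions are reproducible bit-for-bit from
  (profile, exercise, patient profile, seed). The simulator draws stress and
  events from one shared `numpy` Generator per session.

## The patient simulator

The generator emulates exactly the two streams the real system consumes —
nothing else. Latent stress follows a first-order autoregressive pull toward
`baseline + reactivity · pressure` (persistence 0.8–0.85, uniform noise
±0.05), where pressure is the excess of the current level over the
skill-implied comfortable level; readings are clamped to [0, 1]. Events per
tick: hit with probability `min(1, skill · help_benefit^[help active])`, else
distractor error with probability `distractor_susceptibility` when distractors
are present, else idle/cognitive-error by a configured split.

Archetype presets (proficient: skill 0.60, baseline 0.15; average: 0.30/0.35;
struggling: 0.05/0.58 with a high idle share so errors accrue at a realistic
rate rather than saturating instantly) were chosen once so that every distinct
controller output is reachable in simulation: proficient cohorts never need
help, struggling cohorts trigger help on roughly half their steps and cancel
a minority of them. Cohort studies in the test suite use unlimited lives and
no session time limit so that every cancellation is a controller decision
(a lives- or timeout-cancellation can coincide with low stress, where the
difficulty blend legitimately differs). These are engineering parameters, not
claims about clinical populations: the simulator has no fatigue dynamics, no
learning within or across sessions, no EEG artifacts, and its event process is
memoryless given the help state. Passing closed-loop tests therefore show the
*controllers* behave as specified under plausible input statistics — they say
nothing about efficacy with human patients.

## Sessions, scoring, telemetry

Scoring defaults to +10 per hit and −5 per error, floored at zero — the
direction is the documented behavior, the amounts are configurable options.
Lives (cognitive/distractor) decrement per error of their kind; reaching zero
cancels the step; an initial count of 0 disables the mechanism. The
whole-exercise time limit interrupts the running step (recorded as canceled in
its summary) and ends the session incomplete. `repetitions` is honored by the
CLI by running consecutive passes with carryover — progress is never reset.
The `initial_explanation` options are carried in the data model for client
UIs; the engine does not model the explanation pause.

Telemetry is one JSON object per tick (percent completed, activation/error
counters, elapsed time, windowed stress, interaction counters, score, help
flags; the screenshot field is always null here) plus one summary object per
step. Replay recomputes every summary from the samples alone: trailing-quarter
mean of the logged stress series, errors from the final counters, hits from
the final activated count — which is exact because every hit activates one
target while a step is running.

## Problem sizes

Default test and simulation sizes — 1001-point defuzzification grids, 500
random activations against the integration oracle, cohorts of 5 patients × 7
sessions × 6 steps (210 steps per archetype, 200 used) — run the whole suite
in well under a minute on one core while keeping the Monte-Carlo tolerances
(±0.02 on event frequencies) comfortably tight.

## Known limitations

* The shipped membership breakpoints are expert-style defaults, not fitted to
  any data; real deployments should tune them per patient group (the profile
  JSON exists for exactly that).
* Only conjunctive rules are supported; a rule base needing OR must be
  rewritten as multiple rules.
* Singleton consequents are representable but carry (near-)zero mass under
  centroid defuzzification and should not be used as outputs.
* The engine models selection events abstractly; gesture recognition, element
  geometry and rendering are the client's concern.
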