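# fuzzyrehab

Closed-loop fuzzy controllers for adaptive cognitive telerehabilitation.

Home-based cognitive rehabilitation asks a patient to work through serious-game
exercises — selecting target elements on a screen while ignoring distractors —
without a therapist at their side. `fuzzyrehab` implements the supervision layer
that stands in for the therapist: two Mamdani fuzzy inference systems that read
the patient's stress (from a consumer EEG headset's 1 Hz stress metric) and
interaction behavior, and continuously adapt assistance and difficulty.

* **Help controller (FIS4H)** — runs every second during a step. Inputs:
  windowed stress percentage, seconds without a correct selection, consecutive
  errors. Outputs: *do not modify the help*, *activate help* (latched visual
  and/or haptic assistance that only a correct selection releases), or *cancel
  the step* when the patient is clearly unable to finish it.
* **Difficulty controller (FIS4D)** — runs when a step ends. Inputs: average
  stress over the last quarter of the step, the step's errors ratio, and
  whether the step was canceled. Output: a level offset in {−2, −1, 0, +1, +2}
  applied to the next step's base level and clamped to its range; the offset
  after the final step carries over to the next session's first step.

The raw stress signal s(t) ∈ [0, 1] is never used directly. Each reading is
classified against a threshold θ (default 0.5, with s ≥ θ counting as high) and
the controller sees the percentage over the last *N* readings (default 10):

    current_stress = 100 · #high / #total            (sliding window)
    step_errors_ratio = #errors / (#errors + #hits)  (per step)

Inference is standard Mamdani: min-conjunction of antecedents ("Any" matches
everything), min-implication, max-aggregation, centroid defuzzification on a
1001-point grid, and the crisp output maps back to the label with maximal
membership at the centroid.

The package also contains the exercise data model (steps with nested,
superset-consistent difficulty levels and therapist-chosen base levels), the
per-second session engine with telemetry logging, scoring and lives,
cross-session carryover/resume, a stochastic patient simulator that closes the
loop without any hardware, and JSON/JSON-Lines readers and writers for rule
profiles, exercise definitions and session logs.

## Worked example

Simulate a struggling synthetic patient through the built-in six-step demo
exercise, then verify the log replays losslessly:

```bash
$ fuzzyrehab simulate --archetype struggling --seed 7 --out session.jsonl
complete: 6 steps, levels [4, 1, 2, 5, 1, 2], offsets [-1, -1, 0, -1, -1, -1], score 10 -> session.jsonl

$ fuzzyrehab replay session.jsonl
step 1: ok (avg_stress 100.00, errors_ratio 0.556, canceled False, offset -1)
step 2: ok (avg_stress 100.00, errors_ratio 0.600, canceled False, offset -1)
...
```

The patient starts step 1 at the therapist's base level 4; a poor, high-stress
step drives the difficulty controller to −1, so step 2 opens one level below
its base (clamped to level 1), and so on. `replay` recomputes every step
summary and offset from the telemetry samples alone and diffs them against the
logged values.

One-shot inference is available too — a canceled step with a high errors ratio
decodes to the strong difficulty decrease:

```bash
$ fuzzyrehab infer --fis difficulty --input step_average_stress=85 \
    --input step_errors_ratio=0.8 --input step_canceled=1
{"value": 18.783783783783782, "label": "D--", "activated": true, "strengths": [0.0, 0.0, 0.0, 1.0, 1.0]}
```

From Python:

```python
from fuzzyrehab import default_profile, StressWindow, SignalConfig, current_stress

cfg = SignalConfig()                      # 10-reading window, threshold 0.5
window = StressWindow(capacity=cfg.window_size)
for r in [0.4] * 6 + [0.6] * 4:
    window.push(r)
print(current_stress(window, cfg))        # 40.0  (4 of 10 readings are high)
```

## Layout

| Module | Contents |
| --- | --- |
| `fuzzyrehab.fuzzy` | generic Mamdani engine (membership functions, rules, centroid) |
| `fuzzyrehab.signals` | stress windowing, errors ratio, interaction counters |
| `fuzzyrehab.profiles` | rule profiles; shipped default partitions and rule bases |
| `fuzzyrehab.controllers` | help latching, offset decoding, level clamping |
| `fuzzyrehab.session` | exercise model, per-second loop, carryover/resume, telemetry |
| `fuzzyrehab.patients` | stochastic patient simulator and archetype cohorts |
| `fuzzyrehab.io` / `fuzzyrehab.cli` | JSON dialects, validation, `fuzzyrehab` CLI |

Design rationale and modeling assumptions are documented in
[`docs/methods.md`](docs/methods.md).
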