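"""Readers/writers for the three JSON dialects.

Rule profiles and exercise definitions are single JSON documents;
session telemetry is JSON Lines (one object per 1 Hz sample, one summary
object per step, bracketed by a session header and trailer).  Every
document carries a ``format_version`` field and readers reject unknown
major versions.  Validation runs through the pydantic models, so a file
that loads has already satisfied every structural invariant (nested
level supersets, rule/label references, universe bounds, ...); the
JSON-Schema documents under ``fuzzyrehab/schemas`` are generated from
those same models for interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Union

from pydantic import ValidationError

from .errors import FuzzyRehabError
from .profiles import FORMAT_VERSION, RuleProfile, default_profile
from .session import (
    ExerciseDef,
    SessionRecord,
    StepRecord,
    StepSummary,
    TelemetrySample,
)

PathLike = Union[str, Path]


@dataclass
class ValidationReport:
    """Collected problems found while loading/validating a document."""

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add_error(self, path: str, message: str) -> None:
        self.errors.append((path, message))

    def add_warning(self, path: str, message: str) -> None:
        self.warnings.append((path, message))

    def __str__(self) -> str:
        lines = [f"ERROR {p}: {m}" for p, m in self.errors]
        lines += [f"WARNING {p}: {m}" for p, m in self.warnings]
        return "\n".join(lines) or "ok"


class DocumentError(FuzzyRehabError):
    """A document failed validation; carries the report."""

    def __init__(self, message: str, report: ValidationReport):
        super().__init__(f"{message}\n{report}")
        self.report = report


def _report_from_validation_error(exc: ValidationError) -> ValidationReport:
    report = ValidationReport()
    for err in exc.errors():
        loc = "/".join(str(p) for p in err["loc"]) or "<root>"
        report.add_error(loc, err["msg"])
    return report


def _check_version(payload: dict[str, Any], report: ValidationReport) -> None:
    version = str(payload.get("format_version", FORMAT_VERSION))
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        report.add_error(
            "format_version",
            f"unsupported major version {version!r} (supported: "
            f"{FORMAT_VERSION})",
        )


def _load_document(path: PathLike, model: type, kind: str):
    report = ValidationReport()
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        report.add_error("<file>", str(exc))
        raise DocumentError(f"cannot read {kind} {path}", report) from exc
    if not isinstance(payload, dict):
        report.add_error("<root>", f"{kind} document must be a JSON object")
        raise DocumentError(f"invalid {kind} {path}", report)
    _check_version(payload, report)
    if not report.ok:
        raise DocumentError(f"invalid {kind} {path}", report)
    try:
        return model.model_validate(payload)
    except ValidationError as exc:
        raise DocumentError(
            f"invalid {kind} {path}", _report_from_validation_error(exc)
        ) from exc


def load_profile(path: PathLike) -> RuleProfile:
    """Load and fully validate a rule-profile document."""
    profile: RuleProfile = _load_document(path, RuleProfile, "rule profile")
    return profile


def save_profile(profile: RuleProfile, path: PathLike) -> None:
    Path(path).write_text(
        profile.model_dump_json(indent=2) + "\n", encoding="utf-8"
    )


def load_exercise(path: PathLike) -> ExerciseDef:
    """Load and fully validate an exercise definition."""
    exercise: ExerciseDef = _load_document(path, ExerciseDef, "exercise")
    return exercise


def save_exercise(exercise: ExerciseDef, path: PathLike) -> None:
    Path(path).write_text(
        exercise.model_dump_json(indent=2) + "\n", encoding="utf-8"
    )


def validate_profile(path: PathLike) -> ValidationReport:
    """Validate without raising; coverage gaps are reported as warnings."""
    report = ValidationReport()
    try:
        profile = load_profile(path)
    except DocumentError as exc:
        return exc.report
    for fis in (profile.fis4h, profile.fis4d):
        for var in (*fis.inputs, fis.output):
            if any(mf.shape.value != "crisp_singleton" for mf in var.labels):
                gaps = var.coverage_gaps()
                if gaps:
                    report.add_warning(
                        f"{fis.name}/{var.name}",
                        f"{len(gaps)} grid points have no covering label "
                        f"(first at {gaps[0]:g})",
                    )
    return report


def validate_exercise(path: PathLike) -> ValidationReport:
    try:
        load_exercise(path)
    except DocumentError as exc:
        return exc.report
    return ValidationReport()


def packaged_default_profile_path() -> Path:
    """Path of the profile document shipped inside the package."""
    return Path(
        resources.files("fuzzyrehab").joinpath("data/default_profile.json")  # type: ignore[arg-type]
    )


# --- Session telemetry (JSON Lines) --------------------------------------


def write_session(record: SessionRecord, path: PathLike) -> None:
    """Serialize a session as JSON Lines.

    Layout: one ``session_header`` line, then for every step all its
    ``sample`` lines followed by one ``step_summary`` line, and a final
    ``session_end`` line.
    """
    with open(path, "w", encoding="utf-8") as fh:
        header = {
            "kind": "session_header",
            "format_version": record.format_version,
            "exercise_id": record.exercise_id,
            "exercise_options": json.loads(record.options.model_dump_json()),
        }
        fh.write(json.dumps(header) + "\n")
        for step in record.steps:
            for sample in step.samples:
                line = {"kind": "sample", "step_index": step.step_index}
                line.update(json.loads(sample.model_dump_json()))
                fh.write(json.dumps(line) + "\n")
            summary = {
                "kind": "step_summary",
                "step_index": step.step_index,
                "level_played": step.level_played,
                "status": step.status,
                "offset": step.offset,
                "step_average_stress": step.summary.step_average_stress,
                "step_errors_ratio": step.summary.step_errors_ratio,
                "step_canceled": step.summary.step_canceled,
            }
            fh.write(json.dumps(summary) + "\n")
        trailer = {
            "kind": "session_end",
            "final_score": record.final_score,
            "completion_status": record.completion_status,
        }
        fh.write(json.dumps(trailer) + "\n")


def read_session(path: PathLike) -> SessionRecord:
    """Exact inverse of :func:`write_session`."""
    report = ValidationReport()
    header: Optional[dict[str, Any]] = None
    trailer: Optional[dict[str, Any]] = None
    steps: list[StepRecord] = []
    samples: list[TelemetrySample] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
                kind = obj.pop("kind")
                if kind == "session_header":
                    _check_version(obj, report)
                    if not report.ok:
                        raise DocumentError(
                            f"unsupported session log {path}", report
                        )
                    header = obj
                elif kind == "sample":
                    obj.pop("step_index", None)
                    samples.append(TelemetrySample.model_validate(obj))
                elif kind == "step_summary":
                    steps.append(
                        StepRecord(
                            step_index=obj["step_index"],
                            level_played=obj["level_played"],
                            status=obj["status"],
                            offset=obj["offset"],
                            samples=tuple(samples),
                            summary=StepSummary(
                                step_average_stress=obj["step_average_stress"],
                                step_errors_ratio=obj["step_errors_ratio"],
                                step_canceled=obj["step_canceled"],
                            ),
                        )
                    )
                    samples = []
                elif kind == "session_end":
                    trailer = obj
                else:
                    raise ValueError(f"unknown line kind {kind!r}")
            except DocumentError:
                raise
            except (KeyError, ValueError, ValidationError) as exc:
                report.add_error(f"line {lineno}", str(exc))
                raise DocumentError(
                    f"malformed session log {path} at line {lineno}", report
                ) from exc
    if header is None or trailer is None:
        report.add_error("<file>", "missing session header or trailer")
        raise DocumentError(f"incomplete session log {path}", report)
    from .session import ExerciseOptions  # local import avoids cycle at module load

    return SessionRecord(
        exercise_id=header["exercise_id"],
        options=ExerciseOptions.model_validate(header["exercise_options"]),
        steps=tuple(steps),
        final_score=trailer["final_score"],
        completion_status=trailer["completion_status"],
    )


def export_json_schemas(directory: PathLike) -> list[Path]:
    """Write the JSON-Schema documents for all three dialects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, model in (
        ("rule_profile", RuleProfile),
        ("exercise", ExerciseDef),
        ("session_record", SessionRecord),
    ):
        path = directory / f"{name}.schema.json"
        path.write_text(
            json.dumps(model.model_json_schema(), indent=2) + "\n",
            encoding="utf-8",
        )
        written.append(path)
    return written
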