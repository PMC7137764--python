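"""Field validation, dependency rules, and scoreability reporting.

The calculator is defensive by design: values are type- and
domain-checked per field, logical dependencies between fields are
enforced (the shipped rule: Falls = "No" forces Number of Falls to 0),
and a :class:`ValidationReport` reproduces the error/warning split of
the interactive form — malformed values and missing demographics block
(*errors*), missing optional fields merely warn, and ``scoreable`` is
true exactly when there are no errors and completeness has reached the
schema threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

from .assessment import MISSING, Assessment, ResponseError, parse_raw
from .schema import CodingSchema, ItemDefinition

__all__ = [
    "ValidationReport",
    "validate_field",
    "apply_dependencies",
    "check_scoreability",
]


@dataclass(frozen=True)
class ValidationReport:
    """Findings for one assessment; never raises, always reports."""

    errors: tuple[tuple[str, str], ...]
    warnings: tuple[tuple[str, str], ...]
    completeness: float
    scoreable: bool

    def __post_init__(self) -> None:
        # scoreable is fully determined by the findings; enforce the linkage
        expected = not self.errors and self.completeness >= self._threshold_hint
        if self.scoreable != expected:
            raise ValueError("scoreable flag inconsistent with findings")

    _threshold_hint: float = 0.80

    def format(self) -> str:
        lines = []
        for item_id, msg in self.errors:
            lines.append(f"ERROR   [{item_id}] {msg}")
        for item_id, msg in self.warnings:
            lines.append(f"WARNING [{item_id}] {msg}")
        lines.append(f"completeness: {self.completeness:.1%}")
        lines.append(f"scoreable: {'yes' if self.scoreable else 'no'}")
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        return {
            "errors": [{"item_id": i, "message": m} for i, m in self.errors],
            "warnings": [{"item_id": i, "message": m} for i, m in self.warnings],
            "completeness": self.completeness,
            "scoreable": self.scoreable,
        }


def validate_field(item: ItemDefinition, raw_value: Any) -> str | None:
    """Check one raw value against its item; pure.

    Returns ``None`` when the value is acceptable (including missing),
    else a human-readable message naming the field.
    """
    try:
        parse_raw(item, raw_value)
    except ResponseError as exc:
        return str(exc)
    return None


def apply_dependencies(assessment: Assessment) -> Assessment:
    """Apply the schema's dependency rules to a fixed point; idempotent.

    Rules are data in the schema (trigger item, trigger value, target
    item, forced value); chains settle in at most one pass per rule, and
    cyclic declarations are rejected at schema load.
    """
    assessment._apply_dependencies()
    return assessment


def check_scoreability(assessment: Assessment, schema: CodingSchema | None = None) -> ValidationReport:
    """Full pre-scoring audit of one assessment.

    Missing demographics are blocking errors regardless of the
    completeness threshold (the identification page is all-mandatory);
    missing required items warn and count against completeness; missing
    optional items warn only.
    """
    schema = schema or assessment.schema
    errors: list[tuple[str, str]] = []
    warnings: list[tuple[str, str]] = []

    for name in assessment.demographics.missing_fields():
        errors.append((name, f"demographic field '{name}' is required before scoring"))

    # recorded values are validated on entry, but files may arrive unchecked
    for item_id, raw in assessment.responses.items():
        if item_id not in schema:
            errors.append((item_id, "unknown item for this schema"))
            continue
        message = validate_field(schema[item_id], raw)
        if message is not None:
            errors.append((item_id, message))

    for item in schema.items:
        if not item.is_scored:
            continue
        if assessment.responses.get(item.item_id, MISSING) is MISSING:
            if item.required:
                warnings.append((item.item_id, f"required field '{item.label}' is missing"))
            else:
                warnings.append((item.item_id, f"optional field '{item.label}' is missing"))

    comp = assessment.completeness() if schema is assessment.schema else _completeness(assessment, schema)
    scoreable = not errors and comp >= schema.threshold
    return ValidationReport(
        errors=tuple(errors),
        warnings=tuple(warnings),
        completeness=comp,
        scoreable=scoreable,
        _threshold_hint=schema.threshold,
    )


def _completeness(assessment: Assessment, schema: CodingSchema) -> float:
    required = schema.required_scored_items
    if not required:
        return 1.0
    answered = sum(1 for it in required if assessment.responses.get(it.item_id, MISSING) is not MISSING)
    return answered / len(required)
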