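"""Batch assessment tables: one assessment per row, delimited text in/out.

Input columns are the demographic field names followed by item ids
(header-keyed, any order); an empty cell is a missing answer.  The
results table carries, per row, the score to four decimals or the
refusal reason, plus numerator, denominator and completeness.
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path
from typing import Any

import pandas as pd

from .assessment import Assessment, Demographics, ResponseError
from .schema import CodingSchema
from .scoring import ScoreNotComputable, score_assessment
from .validation import apply_dependencies

__all__ = ["read_assessments", "score_table", "assessments_to_frame"]

_DEMO_COLS = (
    "healthcare_number",
    "age",
    "gender",
    "education",
    "clinician_id",
    "assessment_date",
    "assessment_time",
)


def _demographics_from_row(row: dict[str, str]) -> Demographics:
    def cell(name: str) -> str:
        return (row.get(name) or "").strip()

    return Demographics(
        healthcare_number=cell("healthcare_number"),
        age=int(cell("age")) if cell("age") else None,
        gender=cell("gender"),
        education=cell("education"),
        clinician_id=cell("clinician_id"),
        assessment_date=dt.date.fromisoformat(cell("assessment_date"))
        if cell("assessment_date")
        else None,
        assessment_time=dt.time.fromisoformat(cell("assessment_time"))
        if cell("assessment_time")
        else None,
    )


def read_assessments(
    path: str | Path, schema: CodingSchema, strict: bool = True
) -> list[Assessment]:
    """Read a delimited table of assessments (header-keyed by item id).

    With ``strict`` (the default) an out-of-domain cell raises at once;
    with ``strict=False`` the offending raw value is kept on the record
    so :func:`~eficga.validation.check_scoreability` can report it as a
    per-field error instead of aborting the whole file.
    """
    path = Path(path)
    assessments: list[Assessment] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty input file")
        unknown = [
            c for c in reader.fieldnames if c not in _DEMO_COLS and c not in schema
        ]
        if unknown:
            raise ValueError(f"{path}: unknown columns {unknown}")
        for row in reader:
            assessment = Assessment(schema=schema, demographics=_demographics_from_row(row))
            for col, cell in row.items():
                if col in _DEMO_COLS or cell is None or cell.strip() == "":
                    continue
                try:
                    assessment.set_response(col, cell.strip())
                except ResponseError:
                    if strict:
                        raise
                    assessment.responses[col] = cell.strip()  # reported downstream
            apply_dependencies(assessment)
            assessments.append(assessment)
    return assessments


def score_table(assessments: list[Assessment]) -> pd.DataFrame:
    """Score a batch; refusals become rows, not failures."""
    rows: list[dict[str, Any]] = []
    for i, assessment in enumerate(assessments):
        row: dict[str, Any] = {
            "row": i,
            "healthcare_number": assessment.demographics.healthcare_number,
        }
        try:
            result = score_assessment(assessment)
            row.update(
                score=f"{result.score:.4f}",
                numerator=result.numerator,
                denominator=result.denominator,
                completeness=result.completeness,
                refusal_reason="",
            )
        except ScoreNotComputable as refusal:
            row.update(
                score="",
                numerator=None,
                denominator=None,
                completeness=refusal.completeness,
                refusal_reason=str(refusal),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def assessments_to_frame(assessments: list[Assessment], schema: CodingSchema) -> pd.DataFrame:
    """Render assessments back into the batch input layout (for export)."""
    rows = []
    for assessment in assessments:
        row: dict[str, Any] = {}
        demo = assessment.demographics
        for name in _DEMO_COLS:
            value = getattr(demo, name)
            row[name] = "" if value is None else str(value)
        for item in schema.items:
            value = assessment.responses.get(item.item_id)
            row[item.item_id] = "" if value is None else str(value)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_DEMO_COLS) + [it.item_id for it in schema.items])
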