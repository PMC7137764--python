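"""Deficit coding and the eFI-CGA computation.

The frailty index is the deficit-accumulation ratio

    eFI-CGA = sum(x_i) / n

where each answered item contributes a coded deficit x_i in [0, 1] and n
is the total number of deficits under evaluation.  Two special rules
apply:

* **Comorbidity ceiling** — the raw "Number of Problems" count enters the
  numerator capped at ``comorbidity_cap`` (default 18), and the cap itself
  enters the denominator, so the comorbidity tally can never swamp the
  index.
* **Completeness threshold guard** — no score is issued unless at least
  ``threshold`` (default 80%, inclusive) of the required items are
  answered.  At or above the threshold, missing items are ignored: they
  drop out of both numerator and denominator.

Scores are reported to four decimal places, rounded half-away-from-zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Union

from .assessment import MISSING, Assessment, Missing, parse_raw
from .schema import Band, CodingSchema, ItemDefinition

__all__ = [
    "CodedVector",
    "FIResult",
    "ScoreNotComputable",
    "code_response",
    "code_assessment",
    "compute_efi",
    "score_assessment",
    "round4",
]


def round4(value: float) -> float:
    """Round to 4 decimal places, half away from zero."""
    d = Decimal(repr(value))
    sign = -1 if d < 0 else 1
    return float(sign * abs(d).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CodedVector:
    """Per-item coded deficits for one assessment.

    ``coded`` holds one entry per scored non-comorbidity item (value in
    [0, 1] or :data:`MISSING`); the comorbidity count is kept separately
    as its raw value and its capped contribution.
    """

    coded: dict[str, Union[float, Missing]]
    comorbidity_raw: Union[int, Missing]
    comorbidity_contrib: Union[int, Missing]
    cap: int

    def __post_init__(self) -> None:
        for item_id, value in self.coded.items():
            if value is not MISSING and not (0.0 <= value <= 1.0):
                raise ValueError(f"coded value for {item_id!r} outside [0, 1]: {value}")
        if self.comorbidity_contrib is not MISSING and self.comorbidity_contrib > self.cap:
            raise ValueError("comorbidity contribution exceeds the cap")


@dataclass(frozen=True)
class FIResult:
    """An issued eFI-CGA score with its full audit trail."""

    score: float  # rounded to 4 decimal places
    numerator: float  # sum of present deficits (incl. capped comorbidity)
    denominator: float  # deficits under evaluation (present items + cap)
    items_used: tuple[str, ...]
    items_missing: tuple[str, ...]
    completeness: float

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


class ScoreNotComputable(Exception):
    """Refusal to score: completeness fell below the threshold guard.

    Mirrors the calculator's blocking error when fewer than the required
    fraction of fields are answered; carries the observed completeness and
    the missing items so callers can prompt for them.
    """

    def __init__(self, completeness: float, missing_items: tuple[str, ...], threshold: float):
        self.completeness = completeness
        self.missing_items = missing_items
        self.threshold = threshold
        super().__init__(
            f"cannot compute score: {completeness:.0%} of required fields answered "
            f"(threshold {threshold:.0%}); missing: {', '.join(missing_items) or 'none'}"
        )


def code_response(
    item: ItemDefinition, raw_value: Any, cap: int | None = None
) -> Union[float, int, Missing]:
    """Map one raw response to its coded deficit value.

    Missing stays missing.  Categorical items go through the coding map;
    integer items through their bands; the comorbidity count returns
    ``min(raw, cap)``.
    """
    value = parse_raw(item, raw_value)
    if value is MISSING:
        return MISSING
    if item.kind == "categorical":
        return float(item.coding_map[value])  # type: ignore[index]
    if item.kind in ("count", "numeric"):
        for band in item.coding_map:  # type: ignore[union-attr]
            assert isinstance(band, Band)
            if band.covers(value):
                return float(band.coded)
        raise ValueError(f"{item.item_id}: no coding band covers {value}")  # unreachable for valid schema
    if item.kind == "comorbidity_count":
        if cap is None:
            raise ValueError("comorbidity_count coding requires the cap")
        return min(int(value), cap)
    raise ValueError(f"{item.item_id}: non-scored items have no coded value")


def code_assessment(assessment: Assessment, schema: CodingSchema | None = None) -> CodedVector:
    """Code every scored item of the assessment, preserving missingness."""
    schema = schema or assessment.schema
    cap = schema.comorbidity_cap
    coded: dict[str, Union[float, Missing]] = {}
    comorbidity_raw: Union[int, Missing] = MISSING
    comorbidity_contrib: Union[int, Missing] = MISSING
    for item in schema.scored_items:
        raw = assessment.responses.get(item.item_id, MISSING)
        try:
            value = code_response(item, raw, cap=cap)
        except ValueError as exc:
            raise ValueError(f"item {item.item_id!r}: {exc}") from exc
        if item.kind == "comorbidity_count":
            comorbidity_raw = raw if raw is not MISSING else MISSING
            comorbidity_contrib = value  # type: ignore[assignment]
        else:
            coded[item.item_id] = value  # type: ignore[assignment]
    return CodedVector(
        coded=coded,
        comorbidity_raw=comorbidity_raw,
        comorbidity_contrib=comorbidity_contrib,
        cap=cap,
    )


def compute_efi(coded: CodedVector, schema: CodingSchema) -> FIResult:
    """Compute the eFI-CGA from a coded vector, applying both guards.

    Raises :class:`ScoreNotComputable` when completeness (answered
    fraction of required scored items) is below the schema threshold.
    Otherwise missing items are ignored: the denominator counts only
    answered non-comorbidity items, plus the cap when the comorbidity
    count is answered.
    """
    comorbidity_id = schema.comorbidity_item.item_id
    required_ids = [it.item_id for it in schema.required_scored_items]

    def answered(item_id: str) -> bool:
        if item_id == comorbidity_id:
            return coded.comorbidity_contrib is not MISSING
        return coded.coded.get(item_id, MISSING) is not MISSING

    n_required = len(required_ids)
    n_answered = sum(1 for item_id in required_ids if answered(item_id))
    completeness = n_answered / n_required if n_required else 1.0

    all_ids = [it.item_id for it in schema.scored_items]
    items_missing = tuple(item_id for item_id in all_ids if not answered(item_id))
    if completeness < schema.threshold:
        missing_required = tuple(i for i in required_ids if not answered(i))
        raise ScoreNotComputable(completeness, missing_required, schema.threshold)

    numerator = 0.0
    denominator = 0.0
    items_used: list[str] = []
    for item_id, value in coded.coded.items():
        if value is MISSING:
            continue
        numerator += value
        denominator += 1.0
        items_used.append(item_id)
    if coded.comorbidity_contrib is not MISSING:
        numerator += coded.comorbidity_contrib
        denominator += coded.cap
        items_used.append(comorbidity_id)

    return FIResult(
        score=round4(numerator / denominator),
        numerator=numerator,
        denominator=denominator,
        items_used=tuple(items_used),
        items_missing=items_missing,
        completeness=completeness,
    )


def score_assessment(assessment: Assessment, schema: CodingSchema | None = None) -> FIResult:
    """Code and score one assessment, enforcing the demographics gate.

    The identification page must be complete before a score is issued;
    an incomplete page raises :class:`ScoreNotComputable` just like the
    threshold guard.
    """
    schema = schema or assessment.schema
    if not assessment.demographics.complete:
        raise ScoreNotComputable(
            assessment.completeness(),
            assessment.demographics.missing_fields(),
            schema.threshold,
        )
    return compute_efi(code_assessment(assessment, schema), schema)
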