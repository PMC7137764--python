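"""In-memory model of one CGA encounter.

An :class:`Assessment` bundles patient demographics, the item responses,
and per-item clinical follow-up flags.  Responses are validated against
the governing :class:`~eficga.schema.CodingSchema` on entry — an illegal
value never enters the record — and schema-declared dependency rules
(e.g. Falls = "No" forces Number of Falls to 0) are applied immediately.

Missing responses are a distinguished state (:data:`MISSING`), never a
sentinel value inside an item's response domain, so a blank can never be
scored as a zero by accident.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Any, Iterable

from .schema import CodingSchema, IntRange, ItemDefinition

__all__ = [
    "MISSING",
    "Missing",
    "Demographics",
    "Response",
    "ActionFlag",
    "Assessment",
    "ResponseError",
    "UnknownItemError",
    "parse_raw",
    "completeness",
]


class Missing:
    """Singleton marker for an unanswered item."""

    _instance: "Missing | None" = None

    def __new__(cls) -> "Missing":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = Missing()


class ResponseError(ValueError):
    """A raw value outside the item's response domain (record unchanged)."""


class UnknownItemError(KeyError):
    """An item_id that does not resolve in the governing schema."""


@dataclass
class Demographics:
    """Patient/clinician identification collected before the form opens.

    Scoring is gated on all of these being present (the identification
    page must be complete before the assessment form is reachable).
    """

    healthcare_number: str = ""
    age: int | None = None
    gender: str = ""
    education: str = ""
    clinician_id: str = ""
    assessment_date: dt.date | None = None
    assessment_time: dt.time | None = None

    def __post_init__(self) -> None:
        if self.age is not None:
            if not isinstance(self.age, int) or isinstance(self.age, bool):
                raise ResponseError("Age must be an integer")
            if self.age < 0:
                raise ResponseError("Age must be a non-negative integer")

    def missing_fields(self) -> tuple[str, ...]:
        out = []
        for name in ("healthcare_number", "age", "gender", "education",
                     "clinician_id", "assessment_date", "assessment_time"):
            value = getattr(self, name)
            if value is None or value == "":
                out.append(name)
        return tuple(out)

    @property
    def complete(self) -> bool:
        return not self.missing_fields()


@dataclass(frozen=True)
class Response:
    item_id: str
    raw_value: Any  # member of the item's response_domain, or MISSING


@dataclass(frozen=True)
class ActionFlag:
    """A follow-up checkbox on one item, with an optional free-text note."""

    item_id: str
    flagged: bool
    note: str = ""

    def __post_init__(self) -> None:
        if self.note and not self.flagged:
            raise ValueError("a note requires the item to be flagged")


def parse_raw(item: ItemDefinition, raw_value: Any) -> Any:
    """Coerce and validate ``raw_value`` against the item's domain.

    Accepts the typed value or its string rendering (as read back from a
    file); returns the canonical typed value or raises :class:`ResponseError`
    with a message naming the field.
    """
    if raw_value is MISSING or raw_value is None:
        return MISSING
    if item.kind == "categorical":
        value = str(raw_value)
        if value not in item.response_domain:  # type: ignore[operator]
            raise ResponseError(
                f"{item.label}: {raw_value!r} is not one of the allowed choices "
                f"{list(item.response_domain)}"  # type: ignore[arg-type]
            )
        return value
    if item.kind in ("count", "numeric", "comorbidity_count"):
        if isinstance(raw_value, bool) or isinstance(raw_value, float) and not raw_value.is_integer():
            raise ResponseError(f"{item.label}: only integers are accepted")
        try:
            value = int(raw_value)
        except (TypeError, ValueError):
            raise ResponseError(f"{item.label}: only integers are accepted") from None
        domain = item.response_domain
        assert isinstance(domain, IntRange)
        if value not in domain:
            raise ResponseError(
                f"{item.label}: {value} is outside the allowed range {domain.lo}..{domain.hi}"
            )
        return value
    # non_scored free text
    return str(raw_value)


@dataclass
class Assessment:
    """One patient's encounter: demographics, responses, follow-up flags."""

    schema: CodingSchema
    demographics: Demographics = field(default_factory=Demographics)
    responses: dict[str, Any] = field(default_factory=dict)
    action_flags: dict[str, ActionFlag] = field(default_factory=dict)
    created_at: dt.datetime | None = None

    # -- responses -----------------------------------------------------

    def set_response(self, item_id: str, raw_value: Any) -> "Assessment":
        """Record a response; last write wins; dependents updated.

        Rejects unknown items and out-of-domain values without modifying
        the record, then re-applies the schema's dependency rules so
        forced fields (e.g. Number of Falls after Falls = "No") stay
        consistent.
        """
        if item_id not in self.schema:
            raise UnknownItemError(item_id)
        value = parse_raw(self.schema[item_id], raw_value)
        if value is MISSING:
            self.responses.pop(item_id, None)
        else:
            self.responses[item_id] = value
        self._apply_dependencies()
        return self

    def clear_response(self, item_id: str) -> "Assessment":
        if item_id not in self.schema:
            raise UnknownItemError(item_id)
        self.responses.pop(item_id, None)
        self._apply_dependencies()
        return self

    def get(self, item_id: str) -> Any:
        """The recorded raw value, or :data:`MISSING`."""
        if item_id not in self.schema:
            raise UnknownItemError(item_id)
        return self.responses.get(item_id, MISSING)

    def _apply_dependencies(self) -> None:
        # fixed point in <= number-of-rules passes; acyclicity guaranteed by schema
        rules = self.schema.dependencies
        for _ in range(max(1, len(rules))):
            changed = False
            for rule in rules:
                if self.responses.get(rule.when_item, MISSING) == rule.equals:
                    forced = parse_raw(self.schema[rule.set_item], rule.value)
                    if self.responses.get(rule.set_item, MISSING) != forced:
                        self.responses[rule.set_item] = forced
                        changed = True
            if not changed:
                break

    # -- follow-up flags -----------------------------------------------

    def flag_action(self, item_id: str, note: str = "") -> "Assessment":
        """Mark an item as requiring clinical follow-up (multiple allowed)."""
        if item_id not in self.schema:
            raise UnknownItemError(item_id)
        item = self.schema[item_id]
        if not item.action_flaggable:
            raise ResponseError(f"{item.label}: item does not carry a follow-up checkbox")
        self.action_flags[item_id] = ActionFlag(item_id=item_id, flagged=True, note=note)
        return self

    def unflag_action(self, item_id: str) -> "Assessment":
        self.action_flags.pop(item_id, None)
        return self

    def flagged_items(self) -> tuple[ActionFlag, ...]:
        return tuple(
            self.action_flags[it.item_id]
            for it in self.schema.items
            if it.item_id in self.action_flags
        )

    # -- completeness --------------------------------------------------

    def answered_required(self) -> tuple[str, ...]:
        return tuple(
            it.item_id for it in self.schema.required_scored_items if it.item_id in self.responses
        )

    def missing_required(self) -> tuple[str, ...]:
        return tuple(
            it.item_id
            for it in self.schema.required_scored_items
            if it.item_id not in self.responses
        )

    def completeness(self) -> float:
        """Answered fraction of required scored items, in [0, 1]."""
        required = self.schema.required_scored_items
        if not required:
            return 1.0
        return len(self.answered_required()) / len(required)

    # -- bulk construction ---------------------------------------------

    def set_responses(self, values: dict[str, Any] | Iterable[tuple[str, Any]]) -> "Assessment":
        pairs = values.items() if isinstance(values, dict) else values
        for item_id, raw in pairs:
            self.set_response(item_id, raw)
        return self


def completeness(assessment: Assessment, schema: CodingSchema | None = None) -> float:
    """Functional alias for :meth:`Assessment.completeness`."""
    if schema is not None and schema is not assessment.schema:
        required = schema.required_scored_items
        if not required:
            return 1.0
        answered = sum(1 for it in required if it.item_id in assessment.responses)
        return answered / len(required)
    return assessment.completeness()
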