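"""Simulation test cases and the independent scoring oracle.

Conformance of a frailty-index calculator is established against
manually-verifiable ground truth.  This module provides both halves:

* :func:`oracle_score` — a deliberately plain, straight-line transcription
  of the scoring rules (sum the coded deficits, cap the comorbidity
  count, guard on completeness, divide, round).  It shares no code with
  :mod:`eficga.scoring` and exists solely to serve as ground truth.
* :func:`generate_cases` — deterministic generators for the four
  categories of systematic test cases: the completeness threshold guard,
  whole-section missingness, value-range extremes, and a full sweep of
  every raw value's mapping.

The default suite of 8 cases per category (32 in total) can be exported
as a conformance-vector bundle to test third-party implementations.
"""

from __future__ import annotations

import datetime as dt
import decimal
import random
from dataclasses import dataclass
from math import ceil
from typing import Union

from .assessment import MISSING, Assessment, Demographics
from .schema import CodingSchema

__all__ = [
    "CATEGORIES",
    "TestCase",
    "OracleRefusal",
    "oracle_score",
    "generate_cases",
    "generate_suite",
    "make_demographics",
    "random_assessment",
]

CATEGORIES = ("threshold_guard", "section_missing", "value_range", "mapping_sweep")


@dataclass(frozen=True)
class OracleRefusal:
    """The oracle's independent refusal-to-score outcome."""

    completeness: float


@dataclass(frozen=True)
class TestCase:
    case_id: str
    category: str
    assessment: Assessment
    expected: Union[float, OracleRefusal]  # score to 4 dp, or refusal
    seed: int


# ---------------------------------------------------------------------------
# the oracle


def oracle_score(assessment: Assessment, schema: CodingSchema) -> Union[float, OracleRefusal]:
    """Manual-style scoring: exhaustive, no shortcuts, no shared helpers.

    Walks every item of the schema one by one exactly as a person with
    the coding table and a calculator would: look the answer up, write
    down the coded value, add the capped comorbidity count, check the
    completed fraction, then divide and round to four decimals.
    """
    answered_required = 0
    total_required = 0
    deficit_sum = decimal.Decimal(0)
    deficit_count = decimal.Decimal(0)

    for item in schema.items:
        if item.kind == "non_scored":
            continue
        if item.required:
            total_required += 1
        answer = assessment.responses.get(item.item_id, MISSING)
        if answer is MISSING:
            continue
        if item.required:
            answered_required += 1
        if item.kind == "categorical":
            coded = decimal.Decimal(str(item.coding_map[answer]))
            deficit_sum += coded
            deficit_count += 1
        elif item.kind in ("count", "numeric"):
            coded = None
            for band in item.coding_map:
                if band.upto is None or answer <= band.upto:
                    coded = decimal.Decimal(str(band.coded))
                    break
            deficit_sum += coded
            deficit_count += 1
        elif item.kind == "comorbidity_count":
            capped = answer if answer <= schema.comorbidity_cap else schema.comorbidity_cap
            deficit_sum += decimal.Decimal(capped)
            deficit_count += decimal.Decimal(schema.comorbidity_cap)

    if total_required == 0:
        completed_fraction = 1.0
    else:
        completed_fraction = answered_required / total_required
    if completed_fraction < schema.threshold:
        return OracleRefusal(completeness=completed_fraction)

    ratio = deficit_sum / deficit_count
    rounded = ratio.quantize(decimal.Decimal("0.0001"), rounding=decimal.ROUND_HALF_UP)
    return float(rounded)


# ---------------------------------------------------------------------------
# assessment builders


def make_demographics(rng: random.Random | None = None) -> Demographics:
    """A complete, plausible identification page for generated cases."""
    rng = rng or random.Random(0)
    return Demographics(
        healthcare_number=f"HC{rng.randrange(10**8):08d}",
        age=rng.randrange(65, 100),
        gender=rng.choice(["Female", "Male"]),
        education=str(rng.randrange(4, 21)),
        clinician_id=f"CL{rng.randrange(1000):03d}",
        assessment_date=dt.date(2024, 1, 1) + dt.timedelta(days=rng.randrange(365)),
        assessment_time=dt.time(hour=rng.randrange(8, 18), minute=rng.randrange(60)),
    )


def _random_value(item, rng: random.Random):
    domain = item.domain_values()
    return rng.choice(domain) if domain else None


def _fill_all(assessment: Assessment, rng: random.Random) -> None:
    for item in assessment.schema.scored_items:
        assessment.set_response(item.item_id, _random_value(item, rng))


def random_assessment(
    schema: CodingSchema,
    rng: random.Random,
    answer_fraction: float = 1.0,
) -> Assessment:
    """A random assessment answering roughly ``answer_fraction`` of items."""
    assessment = Assessment(schema=schema, demographics=make_demographics(rng))
    for item in schema.scored_items:
        if rng.random() < answer_fraction:
            assessment.set_response(item.item_id, _random_value(item, rng))
    return assessment


def _extreme_value(item, pick: str):
    """The raw value whose coded deficit is minimal/maximal/closest to 0.5."""
    from .scoring import code_response

    if item.kind == "comorbidity_count":
        lo, hi = item.response_domain.lo, item.response_domain.hi
        return {"min": lo, "max": hi, "mid": (lo + hi) // 2}[pick]
    best = None
    for raw in item.domain_values():
        coded = code_response(item, raw)
        key = {"min": coded, "max": -coded, "mid": abs(coded - 0.5)}[pick]
        if best is None or key < best[0]:
            best = (key, raw)
    return best[1]


# ---------------------------------------------------------------------------
# category generators


def _threshold_guard_cases(schema: CodingSchema, count: int, rng: random.Random) -> list[Assessment]:
    """0 %, just-below, exactly-at, just-above threshold, then random fills."""
    required = [it.item_id for it in schema.required_scored_items]
    n = len(required)
    at = ceil(schema.threshold * n)  # smallest answered count meeting the guard
    targets = [0, max(at - 1, 0), at, min(at + 1, n)]
    while len(targets) < count:
        targets.append(rng.randrange(0, n + 1))
    out = []
    for k in targets[:max(count, 4)]:
        assessment = Assessment(schema=schema, demographics=make_demographics(rng))
        chosen = set(rng.sample(required, k))
        for item_id in (i for i in required if i in chosen):
            item = schema[item_id]
            value = _random_value(item, rng)
            # keep the answered count exactly k: if this answer would force an
            # un-chosen dependency target, pick a non-triggering value instead
            for rule in schema.dependencies:
                if rule.when_item == item_id and rule.set_item not in chosen and value == rule.equals:
                    alternatives = [v for v in item.domain_values() if v != rule.equals]
                    if alternatives:
                        value = rng.choice(alternatives)
            assessment.set_response(item_id, value)
        out.append(assessment)
    return out


def _section_missing_cases(schema: CodingSchema, count: int, rng: random.Random) -> list[Assessment]:
    """Blank whole sections while keeping completeness at or above threshold."""
    required = schema.required_scored_items
    n = len(required)
    blankable = []
    for section in schema.sections:
        section_required = [it for it in required if it.section == section]
        if section_required and (n - len(section_required)) / n >= schema.threshold:
            blankable.append(section)
    if not blankable:
        raise ValueError("no section can be blanked without tripping the threshold guard")
    out = []
    for i in range(count):
        section = blankable[i % len(blankable)]
        assessment = Assessment(schema=schema, demographics=make_demographics(rng))
        _fill_all(assessment, rng)
        for item in schema.section_items(section):
            assessment.clear_response(item.item_id)
        assessment._apply_dependencies()
        out.append(assessment)
    return out


def _value_range_cases(schema: CodingSchema, count: int, rng: random.Random) -> list[Assessment]:
    """All-minimum, all-maximum, all-mid codings, then random mixes of the three."""
    picks = ["min", "max", "mid"]
    out = []
    for i in range(count):
        assessment = Assessment(schema=schema, demographics=make_demographics(rng))
        for item in schema.scored_items:
            pick = picks[i] if i < 3 else rng.choice(picks)
            assessment.set_response(item.item_id, _extreme_value(item, pick))
        assessment._apply_dependencies()
        out.append(assessment)
    return out


def _mapping_sweep_cases(schema: CodingSchema, count: int, rng: random.Random) -> list[Assessment]:
    """Every raw value of every item appears in at least one case.

    Each item cycles through its response domain across cases; an item's
    cursor only advances when its assigned value survived the dependency
    rules (a forced target keeps retrying until every value is seen), so
    the suite is as long as full coverage requires and ``count`` acts as
    a minimum.
    """
    domains = {it.item_id: it.domain_values() for it in schema.scored_items}
    cursor = {item_id: 0 for item_id in domains}
    out: list[Assessment] = []
    budget = count + 10 * max(len(d) for d in domains.values())

    def fully_covered() -> bool:
        return all(cursor[i] >= len(domains[i]) for i in cursor)

    while (len(out) < count or not fully_covered()) and len(out) < budget:
        assessment = Assessment(schema=schema, demographics=make_demographics(rng))
        candidates = {}
        for item in schema.scored_items:
            domain = domains[item.item_id]
            candidates[item.item_id] = domain[cursor[item.item_id] % len(domain)]
            assessment.set_response(item.item_id, candidates[item.item_id])
        assessment._apply_dependencies()
        for item_id, candidate in candidates.items():
            if assessment.responses.get(item_id) == candidate:
                cursor[item_id] += 1
        out.append(assessment)
    if not fully_covered():
        raise ValueError("dependency rules prevent full raw-value coverage")
    return out


_GENERATORS = {
    "threshold_guard": _threshold_guard_cases,
    "section_missing": _section_missing_cases,
    "value_range": _value_range_cases,
    "mapping_sweep": _mapping_sweep_cases,
}


def generate_cases(
    schema: CodingSchema,
    category: str,
    count: int = 8,
    seed: int = 0,
) -> list[TestCase]:
    """Deterministic test cases for one category, ground-truthed by the oracle.

    Reproducible bit-for-bit for a given (schema, category, count, seed).
    ``mapping_sweep`` treats ``count`` as a minimum so that every raw
    value of every item is exercised at least once.
    """
    if category not in _GENERATORS:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = random.Random(seed)
    assessments = _GENERATORS[category](schema, count, rng)
    cases = []
    for i, assessment in enumerate(assessments):
        cases.append(
            TestCase(
                case_id=f"{category}-{i:03d}",
                category=category,
                assessment=assessment,
                expected=oracle_score(assessment, schema),
                seed=seed,
            )
        )
    return cases


def generate_suite(
    schema: CodingSchema,
    per_category: int = 8,
    seed: int = 0,
) -> list[TestCase]:
    """The full four-category suite (>= 32 cases at the default size)."""
    suite: list[TestCase] = []
    for offset, category in enumerate(CATEGORIES):
        suite.extend(generate_cases(schema, category, count=per_category, seed=seed + offset))
    return suite
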