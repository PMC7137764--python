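import datetime as dt

import pytest

from eficga import (
    Assessment,
    CodingSchema,
    Demographics,
    IntRange,
    ItemDefinition,
    default_schema,
)

THREE_LEVEL = {"No Problem": 0.0, "Some Problem": 0.5, "Severe Problem": 1.0}


def make_plain_schema(
    n_items: int,
    cap: int = 18,
    threshold: float = 0.80,
    comorbidity_max: int = 30,
) -> CodingSchema:
    """A synthetic schema of n three-level items plus one comorbidity count."""
    items = [
        ItemDefinition(
            item_id=f"item{i:02d}",
            label=f"Item {i}",
            section=f"Section {i // 5}",
            kind="categorical",
            response_domain=tuple(THREE_LEVEL),
            coding_map=dict(THREE_LEVEL),
        )
        for i in range(n_items)
    ]
    items.append(
        ItemDefinition(
            item_id="problems",
            label="Number of Problems",
            section="Medical",
            kind="comorbidity_count",
            response_domain=IntRange(0, comorbidity_max),
        )
    )
    return CodingSchema(items=tuple(items), comorbidity_cap=cap, threshold=threshold)


def make_demographics() -> Demographics:
    return Demographics(
        healthcare_number="HC00000001",
        age=79,
        gender="Female",
        education="12",
        clinician_id="CL001",
        assessment_date=dt.date(2024, 3, 15),
        assessment_time=dt.time(10, 30),
    )


def full_assessment(schema: CodingSchema, level: str = "No Problem", problems: int = 0) -> Assessment:
    """Every scored item answered; categorical items at ``level``."""
    a = Assessment(schema=schema, demographics=make_demographics())
    for item in schema.scored_items:
        if item.kind == "comorbidity_count":
            a.set_response(item.item_id, problems)
        elif item.kind == "categorical" and level in (item.response_domain or ()):
            a.set_response(item.item_id, level)
        else:
            a.set_response(item.item_id, item.domain_values()[0])
    return a


def extreme_assessment(schema: CodingSchema, pick: str) -> Assessment:
    """Every scored item at its minimum- or maximum-deficit raw value."""
    from eficga.fixtures import _extreme_value

    a = Assessment(schema=schema, demographics=make_demographics())
    for item in schema.scored_items:
        a.set_response(item.item_id, _extreme_value(item, pick))
    a._apply_dependencies()
    return a


@pytest.fixture(scope="session")
def schema() -> CodingSchema:
    return default_schema()


@pytest.fixture()
def plain10() -> CodingSchema:
    """10 three-level items + comorbidity (the hand-computation schema)."""
    return make_plain_schema(10)


@pytest.fixture()
def demographics() -> Demographics:
    return make_demographics()
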