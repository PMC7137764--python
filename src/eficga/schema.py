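"""Coding schema: the declarative definition that drives scoring.

A deficit-accumulation frailty index is only as good as its coding scheme:
every assessment item must declare which raw responses are legal and which
deficit value in [0, 1] each response maps to.  This module makes that
scheme a first-class, auditable object.  Schemas are authored as YAML,
loaded into immutable :class:`CodingSchema` objects, and can be exported as
a flat table for clinical audit.

Item kinds
----------
``categorical``
    A fixed set of named choices (radio buttons / drop-downs); the coding
    map assigns each choice a deficit value.
``count`` / ``numeric``
    An integer in a declared range (e.g. number of falls, a cognitive test
    score); coded through ordered *bands* — the first band whose upper
    bound covers the value supplies the coded deficit.
``comorbidity_count``
    The "Number of Problems" tally.  It carries no coding map: the raw
    count enters the numerator directly, capped at ``comorbidity_cap``,
    while the cap itself enters the denominator.  Exactly one such item
    must exist.
``non_scored``
    Recorded but never scored (free text, administrative categories).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import yaml

__all__ = [
    "Band",
    "IntRange",
    "ItemDefinition",
    "DependencyRule",
    "CodingSchema",
    "SchemaError",
    "load_schema",
    "save_schema",
    "schema_to_table",
    "default_schema",
    "KINDS",
]

KINDS = ("categorical", "count", "numeric", "comorbidity_count", "non_scored")


class SchemaError(ValueError):
    """A schema file or schema object violates the schema contract."""


@dataclass(frozen=True)
class IntRange:
    """Closed integer interval ``[lo, hi]`` used as a response domain."""

    lo: int
    hi: int

    def __contains__(self, value: object) -> bool:
        return isinstance(value, int) and not isinstance(value, bool) and self.lo <= value <= self.hi

    def __iter__(self) -> Iterator[int]:
        return iter(range(self.lo, self.hi + 1))

    def __len__(self) -> int:
        return self.hi - self.lo + 1


@dataclass(frozen=True)
class Band:
    """One coding band for integer items: values ``<= upto`` code to ``coded``.

    ``upto=None`` means "no upper bound" and is only legal for the last band.
    """

    upto: int | None
    coded: float

    def covers(self, value: int) -> bool:
        return self.upto is None or value <= self.upto


@dataclass(frozen=True)
class ItemDefinition:
    """One assessment item: its response domain and raw→coded mapping."""

    item_id: str
    label: str
    section: str
    kind: str
    response_domain: tuple[str, ...] | IntRange | None = None
    coding_map: Mapping[str, float] | tuple[Band, ...] | None = None
    required: bool = True
    action_flaggable: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"item {self.item_id!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not isinstance(self.response_domain, tuple) or not self.response_domain:
                raise SchemaError(f"item {self.item_id!r}: categorical items need a non-empty choice list")
            if not isinstance(self.coding_map, Mapping):
                raise SchemaError(f"item {self.item_id!r}: categorical items need a choice→value coding map")
            if set(self.coding_map) != set(self.response_domain):
                raise SchemaError(
                    f"item {self.item_id!r}: coding map keys must exactly equal the response domain"
                )
        elif self.kind in ("count", "numeric"):
            if not isinstance(self.response_domain, IntRange):
                raise SchemaError(f"item {self.item_id!r}: {self.kind} items need an integer range domain")
            if not isinstance(self.coding_map, tuple) or not self.coding_map:
                raise SchemaError(f"item {self.item_id!r}: {self.kind} items need coding bands")
            for i, band in enumerate(self.coding_map):
                if band.upto is None and i != len(self.coding_map) - 1:
                    raise SchemaError(f"item {self.item_id!r}: open band must be last")
            if not any(b.covers(self.response_domain.hi) for b in self.coding_map):
                raise SchemaError(f"item {self.item_id!r}: bands do not cover the response domain")
        elif self.kind == "comorbidity_count":
            if not isinstance(self.response_domain, IntRange):
                raise SchemaError(f"item {self.item_id!r}: comorbidity count needs an integer range domain")
            if self.coding_map is not None:
                raise SchemaError(f"item {self.item_id!r}: comorbidity count carries no coding map")
        else:  # non_scored
            if self.coding_map is not None:
                raise SchemaError(f"item {self.item_id!r}: non-scored items carry no coding map")
            if self.required:
                raise SchemaError(f"item {self.item_id!r}: non-scored items cannot be required")
        for coded in self.coded_values():
            if not (0.0 <= coded <= 1.0) or math.isnan(coded):
                raise SchemaError(f"item {self.item_id!r}: coded value {coded} outside [0, 1]")

    # -- derived views -------------------------------------------------

    @property
    def is_scored(self) -> bool:
        """True when the item contributes a coded deficit to the index."""
        return self.kind in ("categorical", "count", "numeric", "comorbidity_count")

    def coded_values(self) -> tuple[float, ...]:
        if isinstance(self.coding_map, Mapping):
            return tuple(self.coding_map.values())
        if isinstance(self.coding_map, tuple):
            return tuple(b.coded for b in self.coding_map)
        return ()

    def domain_values(self) -> tuple[Any, ...]:
        """Every legal raw value (empty tuple for free-text items)."""
        if self.response_domain is None:
            return ()
        return tuple(self.response_domain)


@dataclass(frozen=True)
class DependencyRule:
    """When ``when_item`` equals ``equals``, force ``set_item`` to ``value``."""

    when_item: str
    equals: Any
    set_item: str
    value: Any


@dataclass(frozen=True)
class CodingSchema:
    """An ordered, validated collection of items plus the scoring constants.

    ``comorbidity_cap`` is the ceiling applied to the comorbidity count
    (default 18, entering both numerator and denominator); ``threshold``
    is the completeness fraction below which no score is issued
    (default 0.80, inclusive at the boundary).
    """

    items: tuple[ItemDefinition, ...]
    dependencies: tuple[DependencyRule, ...] = ()
    comorbidity_cap: int = 18
    threshold: float = 0.80
    schema_version: str = "1"

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        seen: set[str] = set()
        for item_id in ids:
            if item_id in seen:
                raise SchemaError(f"duplicate item_id {item_id!r}")
            seen.add(item_id)
        n_comorbidity = sum(1 for it in self.items if it.kind == "comorbidity_count")
        if n_comorbidity != 1:
            raise SchemaError(
                f"exactly one comorbidity_count item required, found {n_comorbidity}"
            )
        if not (0.0 < self.threshold <= 1.0):
            raise SchemaError(f"threshold {self.threshold} outside (0, 1]")
        if self.comorbidity_cap < 1:
            raise SchemaError(f"comorbidity_cap {self.comorbidity_cap} must be >= 1")
        by_id = {it.item_id: it for it in self.items}
        for rule in self.dependencies:
            for ref in (rule.when_item, rule.set_item):
                if ref not in by_id:
                    raise SchemaError(f"dependency rule references unknown item {ref!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # trigger -> target edges; a cycle would make forced values chase each other
        edges: dict[str, list[str]] = {}
        for rule in self.dependencies:
            edges.setdefault(rule.when_item, []).append(rule.set_item)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for nxt in edges.get(node, ()):
                if state.get(nxt) == 1:
                    raise SchemaError(f"cyclic dependency declaration through {nxt!r}")
                if state.get(nxt) != 2:
                    visit(nxt)
            state[node] = 2

        for node in list(edges):
            if state.get(node) != 2:
                visit(node)

    # -- lookups -------------------------------------------------------

    def __getitem__(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    @property
    def scored_items(self) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items if it.is_scored)

    @property
    def required_scored_items(self) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items if it.is_scored and it.required)

    @property
    def comorbidity_item(self) -> ItemDefinition:
        return next(it for it in self.items if it.kind == "comorbidity_count")

    @property
    def sections(self) -> tuple[str, ...]:
        out: list[str] = []
        for it in self.items:
            if it.section not in out:
                out.append(it.section)
        return tuple(out)

    def section_items(self, section: str) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items if it.section == section)

    def with_items(self, items: Sequence[ItemDefinition]) -> "CodingSchema":
        return replace(self, items=tuple(items))


# ---------------------------------------------------------------------------
# YAML (de)serialisation


def _item_to_dict(item: ItemDefinition) -> dict[str, Any]:
    d: dict[str, Any] = {
        "id": item.item_id,
        "label": item.label,
        "section": item.section,
        "kind": item.kind,
        "required": item.required,
        "action_flaggable": item.action_flaggable,
    }
    if item.kind == "categorical":
        assert isinstance(item.coding_map, Mapping)
        d["choices"] = [{"value": v, "coded": item.coding_map[v]} for v in item.response_domain]
    elif item.kind in ("count", "numeric", "comorbidity_count"):
        assert isinstance(item.response_domain, IntRange)
        d["min"] = item.response_domain.lo
        d["max"] = item.response_domain.hi
        if item.kind != "comorbidity_count":
            assert isinstance(item.coding_map, tuple)
            d["bands"] = [{"upto": b.upto, "coded": b.coded} for b in item.coding_map]
    return d


def _item_from_dict(d: Mapping[str, Any]) -> ItemDefinition:
    try:
        item_id = str(d["id"])
        kind = str(d["kind"])
    except KeyError as exc:
        raise SchemaError(f"item entry missing field {exc}") from exc
    domain: tuple[str, ...] | IntRange | None = None
    coding: Mapping[str, float] | tuple[Band, ...] | None = None
    if kind == "categorical":
        choices = d.get("choices")
        if not isinstance(choices, list):
            raise SchemaError(f"item {item_id!r}: missing choices list")
        domain = tuple(str(c["value"]) for c in choices)
        coding = {str(c["value"]): float(c["coded"]) for c in choices}
    elif kind in ("count", "numeric"):
        domain = IntRange(int(d["min"]), int(d["max"]))
        bands = d.get("bands")
        if not isinstance(bands, list):
            raise SchemaError(f"item {item_id!r}: missing coding bands")
        coding = tuple(
            Band(None if b.get("upto") is None else int(b["upto"]), float(b["coded"])) for b in bands
        )
    elif kind == "comorbidity_count":
        domain = IntRange(int(d["min"]), int(d["max"]))
    return ItemDefinition(
        item_id=item_id,
        label=str(d.get("label", item_id)),
        section=str(d.get("section", "General")),
        kind=kind,
        response_domain=domain,
        coding_map=coding,
        required=bool(d.get("required", kind != "non_scored")),
        action_flaggable=bool(d.get("action_flaggable", False)),
    )


def schema_to_dict(schema: CodingSchema) -> dict[str, Any]:
    return {
        "schema_version": schema.schema_version,
        "comorbidity_cap": schema.comorbidity_cap,
        "threshold": schema.threshold,
        "dependencies": [
            {
                "when_item": r.when_item,
                "equals": r.equals,
                "set_item": r.set_item,
                "value": r.value,
            }
            for r in schema.dependencies
        ],
        "items": [_item_to_dict(it) for it in schema.items],
    }


def schema_from_dict(data: Mapping[str, Any]) -> CodingSchema:
    if not isinstance(data, Mapping) or "items" not in data:
        raise SchemaError("schema document must be a mapping with an 'items' list")
    items = tuple(_item_from_dict(d) for d in data["items"])
    deps = tuple(
        DependencyRule(
            when_item=str(r["when_item"]),
            equals=r["equals"],
            set_item=str(r["set_item"]),
            value=r["value"],
        )
        for r in data.get("dependencies", [])
    )
    return CodingSchema(
        items=items,
        dependencies=deps,
        comorbidity_cap=int(data.get("comorbidity_cap", 18)),
        threshold=float(data.get("threshold", 0.80)),
        schema_version=str(data.get("schema_version", "1")),
    )


def load_schema(path: str | Path) -> CodingSchema:
    """Load and validate a YAML coding schema.

    Loading is deterministic and order-preserving: items score and persist
    in exactly the order they appear in the file.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise SchemaError(f"cannot read schema file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"schema file {path} does not parse: {exc}") from exc
    return schema_from_dict(data)


def save_schema(schema: CodingSchema, path: str | Path) -> None:
    """Write the schema as YAML; ``load_schema`` round-trips it exactly."""
    Path(path).write_text(
        yaml.safe_dump(schema_to_dict(schema), sort_keys=False, allow_unicode=True),
        encoding="utf-8",
    )


def schema_to_table(schema: CodingSchema):
    """Flat audit table: one row per (item, raw value) with its coded value.

    Returns a :class:`pandas.DataFrame` with columns
    ``item_id, section, kind, raw_value, coded_value`` so clinicians and
    vendors can review the full coding scheme in a spreadsheet.
    """
    import pandas as pd

    rows: list[dict[str, Any]] = []
    for item in schema.items:
        if item.kind == "categorical":
            assert isinstance(item.coding_map, Mapping)
            for raw in item.response_domain:  # type: ignore[union-attr]
                rows.append(
                    {
                        "item_id": item.item_id,
                        "section": item.section,
                        "kind": item.kind,
                        "raw_value": raw,
                        "coded_value": item.coding_map[raw],
                    }
                )
        elif item.kind in ("count", "numeric"):
            assert isinstance(item.coding_map, tuple)
            for raw in item.response_domain:  # type: ignore[union-attr]
                coded = next(b.coded for b in item.coding_map if b.covers(raw))
                rows.append(
                    {
                        "item_id": item.item_id,
                        "section": item.section,
                        "kind": item.kind,
                        "raw_value": raw,
                        "coded_value": coded,
                    }
                )
        elif item.kind == "comorbidity_count":
            rows.append(
                {
                    "item_id": item.item_id,
                    "section": item.section,
                    "kind": item.kind,
                    "raw_value": f"{item.response_domain.lo}..{item.response_domain.hi}",  # type: ignore[union-attr]
                    "coded_value": f"min(raw, {schema.comorbidity_cap})",
                }
            )
        else:
            rows.append(
                {
                    "item_id": item.item_id,
                    "section": item.section,
                    "kind": item.kind,
                    "raw_value": "(free text)",
                    "coded_value": "",
                }
            )
    return pd.DataFrame(rows)


def default_schema() -> CodingSchema:
    """The schema shipped with the package (``data/default_schema.yaml``).

    It covers the classical CGA domains — cognition, emotion, motivation,
    health attitude, vision, hearing, speech, sleep, pain, strength,
    balance, mobility, falls, activities of daily living, social
    engagement, medication, control of life — plus a Clinical Frailty
    Scale item and the "Number of Problems" comorbidity count, with the
    Falls → Number-of-Falls dependency rule.
    """
    from importlib.resources import files

    resource = files("eficga").joinpath("data/default_schema.yaml")
    data = yaml.safe_load(resource.read_text(encoding="utf-8"))
    return schema_from_dict(data)
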