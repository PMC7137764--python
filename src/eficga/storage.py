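"""Persistence in the calculator's multi-file, timestamped CSV dialect.

Every save event appends one row (sharing a single date/time stamp and a
bundle id) to each of:

``raw_data.csv``
    The exact user inputs — one TRUE/FALSE column per possible choice of
    every categorical item, verbatim columns for integer and free-text
    items — plus the demographics and the issued score.  This table alone
    reconstructs the assessment.
``coded_data.csv``
    The coded deficit values, one column per scored item, with ``none``
    marking a missing value; the score, numerator, denominator and
    completeness ride along for audit.
``actions.csv``
    One column per flaggable item: ``Action Required`` or ``N/A``.
``actions_summary.txt``
    A text list of flagged items with their free-text notes.

A fifth file, ``snapshot.txt``, appends a plain-text rendering of the full
form state (the headless equivalent of the form screenshot) for recovery
and follow-up comparison.

Saves are atomic per bundle — either every file gains its row or none
does — and a lock file surfaces concurrent access as an explicit error
instead of silent interleaving.
"""

from __future__ import annotations

import csv
import datetime as dt
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

from .assessment import MISSING, Assessment, Demographics
from .schema import CodingSchema
from .scoring import FIResult, ScoreNotComputable, code_assessment

__all__ = [
    "RecordBundle",
    "StorageError",
    "StorageBusyError",
    "StorageFormatError",
    "FILENAMES",
    "save_records",
    "load_records",
    "AutoSaver",
]

FILENAMES = {
    "raw": "raw_data.csv",
    "coded": "coded_data.csv",
    "actions": "actions.csv",
    "summary": "actions_summary.txt",
    "snapshot": "snapshot.txt",
}

NONE_CELL = "none"  # missing scored value in the coded table
NA_CELL = "N/A"  # no follow-up action required
ACTION_CELL = "Action Required"
LOCKFILE = ".eficga.lock"

_DEMOGRAPHIC_FIELDS = (
    "healthcare_number",
    "age",
    "gender",
    "education",
    "clinician_id",
    "assessment_date",
    "assessment_time",
)


class StorageError(Exception):
    """Base class for persistence failures."""


class StorageBusyError(StorageError):
    """Another writer holds the record files (e.g. an autosave in flight)."""


class StorageFormatError(StorageError):
    """Saved files do not match the documented dialect or the schema."""


@dataclass(frozen=True)
class RecordBundle:
    """The row set written by one save event (all share one timestamp)."""

    bundle_id: int
    date: str
    time: str
    raw_row: dict[str, str]
    coded_row: dict[str, str]
    actions_row: dict[str, str]
    summary_text: str
    snapshot_text: str


# ---------------------------------------------------------------------------
# column layout (schema order, stable across saves)


def _raw_header(schema: CodingSchema) -> list[str]:
    cols = ["date", "time", "bundle_id", *_DEMOGRAPHIC_FIELDS]
    for item in schema.items:
        if item.kind == "categorical":
            cols.extend(f"{item.item_id}={choice}" for choice in item.response_domain)  # type: ignore[union-attr]
        else:
            cols.append(item.item_id)
    cols.append("efi_score")
    return cols


def _coded_header(schema: CodingSchema) -> list[str]:
    cols = ["date", "time", "bundle_id"]
    cols.extend(item.item_id for item in schema.scored_items)
    cols.extend(["efi_score", "efi_numerator", "efi_denominator", "completeness"])
    return cols


def _actions_header(schema: CodingSchema) -> list[str]:
    cols = ["date", "time", "bundle_id"]
    cols.extend(item.item_id for item in schema.items if item.action_flaggable)
    return cols


# ---------------------------------------------------------------------------
# row rendering


def _fmt_score(result: Union[FIResult, ScoreNotComputable, None]) -> str:
    if isinstance(result, FIResult):
        return f"{result.score:.4f}"
    return NONE_CELL


def _raw_row(
    assessment: Assessment,
    result: Union[FIResult, ScoreNotComputable, None],
    stamp: tuple[str, str, int],
) -> dict[str, str]:
    date, time, bundle_id = stamp
    demo = assessment.demographics
    row: dict[str, str] = {"date": date, "time": time, "bundle_id": str(bundle_id)}
    for name in _DEMOGRAPHIC_FIELDS:
        value = getattr(demo, name)
        row[name] = "" if value is None else str(value)
    for item in assessment.schema.items:
        raw = assessment.responses.get(item.item_id, MISSING)
        if item.kind == "categorical":
            for choice in item.response_domain:  # type: ignore[union-attr]
                row[f"{item.item_id}={choice}"] = "TRUE" if raw == choice else "FALSE"
        else:
            row[item.item_id] = "" if raw is MISSING else str(raw)
    row["efi_score"] = _fmt_score(result)
    return row


def _coded_row(
    assessment: Assessment,
    result: Union[FIResult, ScoreNotComputable, None],
    stamp: tuple[str, str, int],
) -> dict[str, str]:
    date, time, bundle_id = stamp
    schema = assessment.schema
    coded = code_assessment(assessment, schema)
    row: dict[str, str] = {"date": date, "time": time, "bundle_id": str(bundle_id)}
    comorbidity_id = schema.comorbidity_item.item_id
    for item in schema.scored_items:
        if item.item_id == comorbidity_id:
            value = coded.comorbidity_contrib
        else:
            value = coded.coded[item.item_id]
        row[item.item_id] = NONE_CELL if value is MISSING else f"{float(value):g}"
    row["efi_score"] = _fmt_score(result)
    if isinstance(result, FIResult):
        row["efi_numerator"] = repr(result.numerator)
        row["efi_denominator"] = repr(result.denominator)
        row["completeness"] = repr(result.completeness)  # full precision round trip
    else:
        row["efi_numerator"] = NONE_CELL
        row["efi_denominator"] = NONE_CELL
        row["completeness"] = repr(assessment.completeness())
    return row


def _actions_row(assessment: Assessment, stamp: tuple[str, str, int]) -> dict[str, str]:
    date, time, bundle_id = stamp
    row: dict[str, str] = {"date": date, "time": time, "bundle_id": str(bundle_id)}
    for item in assessment.schema.items:
        if not item.action_flaggable:
            continue
        flag = assessment.action_flags.get(item.item_id)
        row[item.item_id] = ACTION_CELL if flag is not None and flag.flagged else NA_CELL
    return row


def _summary_block(assessment: Assessment, stamp: tuple[str, str, int]) -> str:
    date, time, bundle_id = stamp
    lines = [f"=== {date} {time} bundle {bundle_id} ==="]
    flags = assessment.flagged_items()
    if not flags:
        lines.append("(no actions required)")
    for flag in flags:
        lines.append(f"{flag.item_id}\t{flag.note}")
    return "\n".join(lines) + "\n"


def _snapshot_block(
    assessment: Assessment,
    result: Union[FIResult, ScoreNotComputable, None],
    stamp: tuple[str, str, int],
) -> str:
    date, time, bundle_id = stamp
    schema = assessment.schema
    demo = assessment.demographics
    lines = [f"=== Assessment snapshot — {date} {time} (bundle {bundle_id}) ==="]
    for name in _DEMOGRAPHIC_FIELDS:
        value = getattr(demo, name)
        lines.append(f"{name}: {'' if value is None else value}")
    for section in schema.sections:
        lines.append(f"-- {section} --")
        for item in schema.section_items(section):
            raw = assessment.responses.get(item.item_id, MISSING)
            shown = "(missing)" if raw is MISSING else str(raw)
            flag = assessment.action_flags.get(item.item_id)
            suffix = f"  [FOLLOW UP: {flag.note or 'yes'}]" if flag and flag.flagged else ""
            lines.append(f"{item.label}: {shown}{suffix}")
    if isinstance(result, FIResult):
        lines.append(f"eFI-CGA score: {result.score:.4f}")
    elif isinstance(result, ScoreNotComputable):
        lines.append(f"eFI-CGA score: not computable ({result.completeness:.0%} complete)")
    else:
        lines.append("eFI-CGA score: not calculated")
    return "\n".join(lines) + "\n\n"


# ---------------------------------------------------------------------------
# save


def _next_bundle_id(raw_path: Path) -> int:
    if not raw_path.exists():
        return 1
    with raw_path.open(newline="", encoding="utf-8") as fh:
        return sum(1 for _ in csv.reader(fh))  # header row makes this rows+1


def _append_csv_atomic(path: Path, header: list[str], row: dict[str, str]) -> Path:
    """Stage the appended table into a temp file; caller commits via replace."""
    tmp = path.with_suffix(path.suffix + ".tmp")
    existing_rows: list[dict[str, str]] = []
    if path.exists():
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(reader.fieldnames) != set(header):
                raise StorageFormatError(
                    f"{path.name}: existing columns do not match the schema layout"
                )
            existing_rows = list(reader)
    with tmp.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=header)
        writer.writeheader()
        for r in existing_rows:
            writer.writerow(r)
        writer.writerow(row)
    return tmp


def _append_text_atomic(path: Path, block: str) -> Path:
    tmp = path.with_suffix(path.suffix + ".tmp")
    existing = path.read_text(encoding="utf-8") if path.exists() else ""
    tmp.write_text(existing + block, encoding="utf-8")
    return tmp


def save_records(
    assessment: Assessment,
    result: Union[FIResult, ScoreNotComputable, None],
    destination: str | Path,
    when: dt.datetime | None = None,
    filenames: dict[str, str] | None = None,
) -> RecordBundle:
    """Append one timestamped save of the assessment to the record files.

    All five files are staged first and committed together; a failure
    while staging leaves every file untouched.  ``when`` injects the save
    timestamp (defaults to now).  The issued score, when present, is
    written to both the raw and the coded table.
    """
    destination = Path(destination)
    if not destination.is_dir():
        raise StorageError(f"destination {destination} is not a directory")
    if not os.access(destination, os.W_OK):
        raise StorageError(f"destination {destination} is not writable")
    names = {**FILENAMES, **(filenames or {})}
    when = when or dt.datetime.now()
    schema = assessment.schema

    lock = destination / LOCKFILE
    try:
        fd = os.open(lock, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
    except FileExistsError:
        raise StorageBusyError(
            f"record files in {destination} are in use (lock file {LOCKFILE} present)"
        ) from None
    try:
        raw_path = destination / names["raw"]
        stamp = (when.date().isoformat(), when.time().replace(microsecond=0).isoformat(),
                 _next_bundle_id(raw_path))
        bundle = RecordBundle(
            bundle_id=stamp[2],
            date=stamp[0],
            time=stamp[1],
            raw_row=_raw_row(assessment, result, stamp),
            coded_row=_coded_row(assessment, result, stamp),
            actions_row=_actions_row(assessment, stamp),
            summary_text=_summary_block(assessment, stamp),
            snapshot_text=_snapshot_block(assessment, result, stamp),
        )
        staged: list[tuple[Path, Path]] = []
        staged.append(
            (_append_csv_atomic(raw_path, _raw_header(schema), bundle.raw_row), raw_path)
        )
        coded_path = destination / names["coded"]
        staged.append(
            (_append_csv_atomic(coded_path, _coded_header(schema), bundle.coded_row), coded_path)
        )
        actions_path = destination / names["actions"]
        staged.append(
            (_append_csv_atomic(actions_path, _actions_header(schema), bundle.actions_row), actions_path)
        )
        staged.append(
            (_append_text_atomic(destination / names["summary"], bundle.summary_text),
             destination / names["summary"])
        )
        staged.append(
            (_append_text_atomic(destination / names["snapshot"], bundle.snapshot_text),
             destination / names["snapshot"])
        )
        for tmp, final in staged:  # commit only once every file staged cleanly
            os.replace(tmp, final)
    finally:
        os.close(fd)
        os.unlink(lock)
    return bundle


# ---------------------------------------------------------------------------
# load


def _parse_notes(summary_path: Path) -> dict[int, dict[str, str]]:
    """bundle_id -> {item_id: note} from the actions summary file."""
    notes: dict[int, dict[str, str]] = {}
    if not summary_path.exists():
        return notes
    current: int | None = None
    for line in summary_path.read_text(encoding="utf-8").splitlines():
        if line.startswith("===") and "bundle" in line:
            current = int(line.rstrip("= ").split("bundle")[-1].strip())
            notes[current] = {}
        elif current is not None and "\t" in line:
            item_id, note = line.split("\t", 1)
            notes[current][item_id] = note
    return notes


def _read_rows(path: Path, expected_header: list[str]) -> list[dict[str, str]]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, restkey="__extra__")
        if reader.fieldnames is None:
            raise StorageFormatError(f"{path.name}: empty file")
        missing = set(expected_header) - set(reader.fieldnames)
        extra = set(reader.fieldnames) - set(expected_header)
        if missing or extra:
            raise StorageFormatError(
                f"{path.name}: columns do not match the schema layout "
                f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
            )
        rows = []
        for i, row in enumerate(reader, start=2):
            if "__extra__" in row or any(v is None for v in row.values()):
                raise StorageFormatError(f"{path.name}: malformed row at line {i}")
            rows.append(row)
        return rows


def _assessment_from_raw_row(row: dict[str, str], schema: CodingSchema) -> Assessment:
    demo_kwargs: dict[str, Any] = {}
    for name in _DEMOGRAPHIC_FIELDS:
        cell = row[name]
        if cell == "":
            demo_kwargs[name] = None if name in ("age", "assessment_date", "assessment_time") else ""
        elif name == "age":
            demo_kwargs[name] = int(cell)
        elif name == "assessment_date":
            demo_kwargs[name] = dt.date.fromisoformat(cell)
        elif name == "assessment_time":
            demo_kwargs[name] = dt.time.fromisoformat(cell)
        else:
            demo_kwargs[name] = cell
    assessment = Assessment(schema=schema, demographics=Demographics(**demo_kwargs))
    for item in schema.items:
        if item.kind == "categorical":
            chosen = [c for c in item.response_domain if row[f"{item.item_id}={c}"] == "TRUE"]  # type: ignore[union-attr]
            if len(chosen) > 1:
                raise StorageFormatError(
                    f"raw table: multiple TRUE cells for item {item.item_id!r}"
                )
            if chosen:
                assessment.set_response(item.item_id, chosen[0])
        else:
            cell = row[item.item_id]
            if cell != "":
                value: Any = cell if item.kind == "non_scored" else int(cell)
                assessment.set_response(item.item_id, value)
    return assessment


def load_records(
    path: str | Path,
    schema: CodingSchema,
    filenames: dict[str, str] | None = None,
) -> list[tuple[Assessment, Union[FIResult, ScoreNotComputable, None]]]:
    """Reload every saved row from a records directory, ordered by save time.

    Parsing is header-keyed, so column order in the files is irrelevant;
    a header that does not match the schema's layout (the classic
    wrong-column-ordering corruption) is reported, never guessed at.
    """
    directory = Path(path)
    names = {**FILENAMES, **(filenames or {})}
    raw_path = directory / names["raw"]
    if not raw_path.exists():
        raise StorageError(f"no raw data file at {raw_path}")
    raw_rows = _read_rows(raw_path, _raw_header(schema))
    coded_rows = {r["bundle_id"]: r for r in _read_rows(directory / names["coded"], _coded_header(schema))} \
        if (directory / names["coded"]).exists() else {}
    actions_rows = {r["bundle_id"]: r for r in _read_rows(directory / names["actions"], _actions_header(schema))} \
        if (directory / names["actions"]).exists() else {}
    notes = _parse_notes(directory / names["summary"])

    records: list[tuple[Assessment, Union[FIResult, ScoreNotComputable, None]]] = []
    raw_rows.sort(key=lambda r: (r["date"], r["time"], int(r["bundle_id"])))
    for row in raw_rows:
        assessment = _assessment_from_raw_row(row, schema)
        bundle_id = row["bundle_id"]
        action_row = actions_rows.get(bundle_id, {})
        bundle_notes = notes.get(int(bundle_id), {})
        for item in schema.items:
            if item.action_flaggable and action_row.get(item.item_id) == ACTION_CELL:
                assessment.flag_action(item.item_id, bundle_notes.get(item.item_id, ""))
        result: Union[FIResult, ScoreNotComputable, None]
        coded_row = coded_rows.get(bundle_id)
        if coded_row is None or coded_row["efi_score"] == NONE_CELL:
            comp = float(coded_row["completeness"]) if coded_row else assessment.completeness()
            if comp < schema.threshold:
                result = ScoreNotComputable(comp, assessment.missing_required(), schema.threshold)
            else:
                result = None
        else:
            comorbidity_id = schema.comorbidity_item.item_id
            used, miss = [], []
            for item in schema.scored_items:
                cell = coded_row[item.item_id]
                if cell == NONE_CELL:
                    miss.append(item.item_id)
                elif item.item_id != comorbidity_id:
                    used.append(item.item_id)
            if coded_row[comorbidity_id] != NONE_CELL:
                used.append(comorbidity_id)  # scoring lists the comorbidity last
            result = FIResult(
                score=float(coded_row["efi_score"]),
                numerator=float(coded_row["efi_numerator"]),
                denominator=float(coded_row["efi_denominator"]),
                items_used=tuple(used),
                items_missing=tuple(miss),
                completeness=float(coded_row["completeness"]),
            )
        records.append((assessment, result))
    return records


# ---------------------------------------------------------------------------
# autosave


@dataclass
class AutoSaver:
    """Caller-owned periodic save hook (default cadence: every 3 minutes).

    The calculator saves in the background on a timer; headless callers
    own the timer and call :meth:`tick` — a save happens only when the
    interval has elapsed and, with ``skip_if_unchanged`` (the default),
    when the form state actually changed since the last save.
    """

    assessment: Assessment
    destination: Path
    interval: float = 180.0
    skip_if_unchanged: bool = True
    result_provider: Any = None  # callable () -> FIResult | ScoreNotComputable | None
    _last_save: dt.datetime | None = field(default=None, repr=False)
    _last_state: Any = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("autosave interval must be positive")
        self.destination = Path(self.destination)

    def _state_key(self) -> tuple:
        return (
            tuple(sorted(self.assessment.responses.items())),
            tuple(sorted((k, v.note) for k, v in self.assessment.action_flags.items())),
        )

    def tick(self, now: dt.datetime | None = None) -> RecordBundle | None:
        """Save if due; returns the bundle written, or None if skipped."""
        now = now or dt.datetime.now()
        if self._last_save is not None and (now - self._last_save).total_seconds() < self.interval:
            return None
        state = self._state_key()
        if self.skip_if_unchanged and state == self._last_state:
            return None
        result = self.result_provider() if callable(self.result_provider) else None
        bundle = save_records(self.assessment, result, self.destination, when=now)
        self._last_save = now
        self._last_state = state
        return bundle
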