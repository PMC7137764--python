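"""Record persistence: the four-file CSV dialect, atomicity, autosave."""

import csv
import datetime as dt
import os

import pytest

from eficga import (
    Assessment,
    AutoSaver,
    ScoreNotComputable,
    StorageBusyError,
    StorageError,
    StorageFormatError,
    load_records,
    save_records,
    score_assessment,
)
from eficga.storage import LOCKFILE

from conftest import full_assessment, make_demographics, make_plain_schema

WHEN = dt.datetime(2026, 9, 26, 10, 0, 0)


def scored(assessment):
    try:
        return score_assessment(assessment)
    except ScoreNotComputable as refusal:
        return refusal


class TestRoundTrip:
    def test_save_then_load_reproduces_assessment_and_score(self, schema, tmp_path):
        a = full_assessment(schema, problems=6)
        a.set_response("motivation", "Usual")
        a.flag_action("mobility", "refer to physiotherapy")
        a.flag_action("hearing", "")
        result = score_assessment(a)
        save_records(a, result, tmp_path, when=WHEN)
        (a2, r2), = load_records(tmp_path, schema)
        assert a2.responses == a.responses
        assert a2.demographics == a.demographics
        assert a2.action_flags == a.action_flags
        assert r2 == result

    def test_refusal_round_trips(self, schema, tmp_path):
        a = Assessment(schema=schema, demographics=make_demographics())
        a.set_response("pain", "Mild")
        refusal = scored(a)
        assert isinstance(refusal, ScoreNotComputable)
        save_records(a, refusal, tmp_path, when=WHEN)
        (a2, r2), = load_records(tmp_path, schema)
        assert isinstance(r2, ScoreNotComputable)
        assert r2.completeness == refusal.completeness
        assert a2.responses == a.responses

    def test_two_saves_two_ordered_rows(self, schema, tmp_path):
        a = full_assessment(schema, problems=2)
        save_records(a, scored(a), tmp_path, when=WHEN)
        a.set_response("motivation", "Low")
        save_records(a, scored(a), tmp_path, when=WHEN + dt.timedelta(minutes=30))
        records = load_records(tmp_path, schema)
        assert len(records) == 2
        assert records[0][0].get("motivation") != "Low"
        assert records[1][0].get("motivation") == "Low"

    def test_reloaded_scores_equal_recomputed(self, schema, tmp_path):
        a = full_assessment(schema, problems=9)
        save_records(a, scored(a), tmp_path, when=WHEN)
        (a2, r2), = load_records(tmp_path, schema)
        assert score_assessment(a2).score == r2.score


class TestDialectConventions:
    def test_missing_item_written_as_none_in_coded_table(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        a.clear_response("sleep")
        bundle = save_records(a, scored(a), tmp_path, when=WHEN)
        assert bundle.coded_row["sleep"] == "none"
        others = [v for k, v in bundle.coded_row.items()
                  if k not in ("date", "time", "bundle_id", "sleep", "efi_score",
                               "efi_numerator", "efi_denominator", "completeness")]
        assert "none" not in others

    def test_unflagged_items_written_as_na(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        bundle = save_records(a, scored(a), tmp_path, when=WHEN)
        action_cells = {k: v for k, v in bundle.actions_row.items()
                        if k not in ("date", "time", "bundle_id")}
        assert set(action_cells.values()) == {"N/A"}

    def test_flagged_item_written_as_action_required(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        a.flag_action("appetite", "dietitian referral")
        bundle = save_records(a, scored(a), tmp_path, when=WHEN)
        assert bundle.actions_row["appetite"] == "Action Required"
        assert "dietitian referral" in bundle.summary_text

    def test_raw_table_uses_true_false_choice_columns(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        a.set_response("motivation", "Usual")
        bundle = save_records(a, scored(a), tmp_path, when=WHEN)
        assert bundle.raw_row["motivation=Usual"] == "TRUE"
        assert bundle.raw_row["motivation=High"] == "FALSE"

    def test_score_saved_to_both_raw_and_coded_tables(self, schema, tmp_path):
        a = full_assessment(schema, problems=4)
        result = score_assessment(a)
        bundle = save_records(a, result, tmp_path, when=WHEN)
        assert bundle.raw_row["efi_score"] == f"{result.score:.4f}"
        assert bundle.coded_row["efi_score"] == f"{result.score:.4f}"

    def test_all_tables_share_one_timestamp(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        bundle = save_records(a, scored(a), tmp_path, when=WHEN)
        stamps = {
            (bundle.raw_row["date"], bundle.raw_row["time"]),
            (bundle.coded_row["date"], bundle.coded_row["time"]),
            (bundle.actions_row["date"], bundle.actions_row["time"]),
        }
        assert stamps == {("2026-09-26", "10:00:00")}

    def test_column_order_is_schema_order_and_stable(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        save_records(a, scored(a), tmp_path, when=WHEN)
        with (tmp_path / "coded_data.csv").open(newline="") as fh:
            header_before = next(csv.reader(fh))
        save_records(a, scored(a), tmp_path, when=WHEN + dt.timedelta(minutes=5))
        with (tmp_path / "coded_data.csv").open(newline="") as fh:
            header_after = next(csv.reader(fh))
        assert header_before == header_after
        expected = ["date", "time", "bundle_id"] + [i.item_id for i in schema.scored_items]
        assert header_before[: len(expected)] == expected


class TestRobustness:
    def test_shuffled_columns_load_by_header(self, schema, tmp_path):
        a = full_assessment(schema, problems=2)
        save_records(a, scored(a), tmp_path, when=WHEN)
        raw = tmp_path / "raw_data.csv"
        with raw.open(newline="") as fh:
            rows = list(csv.reader(fh))
        order = list(range(len(rows[0])))[::-1]  # reverse every column
        with raw.open("w", newline="") as fh:
            csv.writer(fh).writerows([[row[i] for i in order] for row in rows])
        (a2, _), = load_records(tmp_path, schema)
        assert a2.responses == a.responses

    def test_truncated_row_reports_line_number(self, schema, tmp_path):
        a = full_assessment(schema, problems=2)
        save_records(a, scored(a), tmp_path, when=WHEN)
        raw = tmp_path / "raw_data.csv"
        text = raw.read_text()
        raw.write_text(text[: text.rfind(",") - 40])  # chop the data row
        with pytest.raises(StorageFormatError, match="line 2"):
            load_records(tmp_path, schema)

    def test_wrong_columns_detected_not_guessed(self, tmp_path, schema):
        a = full_assessment(schema, problems=2)
        save_records(a, scored(a), tmp_path, when=WHEN)
        other = make_plain_schema(4)
        with pytest.raises(StorageFormatError, match="columns"):
            load_records(tmp_path, other)

    def test_concurrent_writer_surfaces_busy_error(self, schema, tmp_path):
        (tmp_path / LOCKFILE).touch()
        a = full_assessment(schema, problems=1)
        with pytest.raises(StorageBusyError):
            save_records(a, scored(a), tmp_path, when=WHEN)

    def test_unwritable_destination_is_an_error(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        with pytest.raises(StorageError):
            save_records(a, scored(a), tmp_path / "does_not_exist", when=WHEN)

    def test_failed_save_leaves_no_partial_bundle(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        save_records(a, scored(a), tmp_path, when=WHEN)
        # corrupt one table's header so the next append fails while staging
        coded = tmp_path / "coded_data.csv"
        coded.write_text("bogus,header\n1,2\n")
        raw_before = (tmp_path / "raw_data.csv").read_text()
        with pytest.raises(StorageFormatError):
            save_records(a, scored(a), tmp_path, when=WHEN + dt.timedelta(minutes=5))
        assert (tmp_path / "raw_data.csv").read_text() == raw_before


class TestAutoSaver:
    def test_default_interval_is_180_seconds(self, schema, tmp_path):
        saver = AutoSaver(full_assessment(schema, problems=1), tmp_path)
        assert saver.interval == 180.0

    def test_tick_respects_interval(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        saver = AutoSaver(a, tmp_path)
        t0 = WHEN
        assert saver.tick(t0) is not None
        a.set_response("motivation", "Low")
        assert saver.tick(t0 + dt.timedelta(seconds=60)) is None  # too soon
        assert saver.tick(t0 + dt.timedelta(seconds=180)) is not None

    def test_unchanged_state_skipped_by_default(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        saver = AutoSaver(a, tmp_path)
        assert saver.tick(WHEN) is not None
        assert saver.tick(WHEN + dt.timedelta(seconds=400)) is None
        a.flag_action("pain", "review")
        assert saver.tick(WHEN + dt.timedelta(seconds=800)) is not None

    def test_skip_if_unchanged_off_saves_every_interval(self, schema, tmp_path):
        a = full_assessment(schema, problems=1)
        saver = AutoSaver(a, tmp_path, skip_if_unchanged=False)
        assert saver.tick(WHEN) is not None
        assert saver.tick(WHEN + dt.timedelta(seconds=200)) is not None
        assert len(load_records(tmp_path, schema)) == 2

    def test_non_positive_interval_rejected(self, schema, tmp_path):
        with pytest.raises(ValueError):
            AutoSaver(full_assessment(schema), tmp_path, interval=0)
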