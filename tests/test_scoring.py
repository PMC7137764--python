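"""The eFI-CGA computation: coding, ceiling, threshold guard, rounding."""

import dataclasses
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eficga import (
    MISSING,
    Assessment,
    ScoreNotComputable,
    code_assessment,
    code_response,
    compute_efi,
    score_assessment,
)

from conftest import full_assessment, make_demographics, make_plain_schema


class TestCodeResponse:
    @pytest.mark.parametrize(
        "raw, expected", [("High", 0.0), ("Usual", 0.5), ("Low", 1.0)]
    )
    def test_motivation_three_levels(self, schema, raw, expected):
        assert code_response(schema["motivation"], raw) == expected

    @pytest.mark.parametrize("raw, expected", [(25, 18), (18, 18), (19, 18), (0, 0), (7, 7)])
    def test_comorbidity_count_capped_at_18(self, schema, raw, expected):
        item = schema.comorbidity_item
        assert code_response(item, raw, cap=schema.comorbidity_cap) == expected

    @pytest.mark.parametrize("raw, expected", [(30, 0.0), (25, 0.0), (24, 0.5), (20, 0.5), (19, 1.0), (0, 1.0)])
    def test_banded_numeric_item(self, schema, raw, expected):
        assert code_response(schema["cognitive_score"], raw) == expected

    def test_missing_stays_missing(self, schema):
        assert code_response(schema["motivation"], MISSING) is MISSING

    def test_out_of_domain_raises(self, schema):
        from eficga import ResponseError

        with pytest.raises(ResponseError):
            code_response(schema["motivation"], "Medium")


class TestCodeAssessment:
    def test_full_form_has_no_missing_entries(self, schema):
        coded = code_assessment(full_assessment(schema, problems=3))
        assert all(v is not MISSING for v in coded.coded.values())
        assert coded.comorbidity_raw == 3 and coded.comorbidity_contrib == 3

    def test_blank_section_entries_missing_others_coded(self, schema):
        a = full_assessment(schema, problems=3)
        for item in schema.section_items("Mobility"):
            a.clear_response(item.item_id)
        coded = code_assessment(a)
        for item in schema.section_items("Mobility"):
            assert coded.coded[item.item_id] is MISSING
        assert coded.coded["motivation"] is not MISSING

    def test_empty_form_all_missing(self, schema):
        coded = code_assessment(Assessment(schema=schema))
        assert all(v is MISSING for v in coded.coded.values())
        assert coded.comorbidity_contrib is MISSING


class TestComputeEfi:
    def test_hand_computed_mixed_case(self, plain10):
        """10 items: four coded 1, one 0.5, five 0; comorbidity 5.

        By the deficit-ratio formula: (4*1 + 0.5 + 5) / (10 + 18)
        = 9.5 / 28 = 0.33928..., i.e. 0.3393 at four decimals.
        """
        a = Assessment(schema=plain10, demographics=make_demographics())
        levels = ["Severe Problem"] * 4 + ["Some Problem"] + ["No Problem"] * 5
        for i, level in enumerate(levels):
            a.set_response(f"item{i:02d}", level)
        a.set_response("problems", 5)
        result = score_assessment(a)
        assert result.score == 0.3393
        assert result.numerator == pytest.approx(9.5)
        assert result.denominator == pytest.approx(28.0)

    def test_all_minimum_deficit_form_scores_zero(self, schema):
        from conftest import extreme_assessment

        result = score_assessment(extreme_assessment(schema, "min"))
        assert result.score == 0.0 and result.numerator == 0.0

    def test_all_maximum_deficit_form_scores_one(self, schema):
        from conftest import extreme_assessment

        result = score_assessment(extreme_assessment(schema, "max"))
        assert result.score == 1.0
        assert result.numerator == result.denominator

    def test_all_zero_plain_form(self, plain10):
        result = score_assessment(full_assessment(plain10, "No Problem", problems=0))
        assert result.score == 0.0 and result.numerator == 0.0

    def test_refusal_below_threshold_carries_details(self):
        schema = make_plain_schema(19)  # 20 required items
        a = Assessment(schema=schema, demographics=make_demographics())
        for i in range(15):  # 75 % complete
            a.set_response(f"item{i:02d}", "No Problem")
        with pytest.raises(ScoreNotComputable) as exc:
            score_assessment(a)
        assert exc.value.completeness == pytest.approx(0.75)
        assert "problems" in exc.value.missing_items

    def test_boundary_exactly_at_threshold_computes(self):
        schema = make_plain_schema(19)  # 20 required, threshold at 16
        a = Assessment(schema=schema, demographics=make_demographics())
        for i in range(16):
            a.set_response(f"item{i:02d}", "Some Problem")
        result = score_assessment(a)
        assert result.completeness == pytest.approx(0.80)
        # 16 answered at 0.5, comorbidity missing: 8 / 16
        assert result.score == 0.5

    def test_one_fewer_than_threshold_refuses(self):
        schema = make_plain_schema(19)
        a = Assessment(schema=schema, demographics=make_demographics())
        for i in range(15):
            a.set_response(f"item{i:02d}", "Some Problem")
        with pytest.raises(ScoreNotComputable):
            score_assessment(a)

    def test_missing_comorbidity_drops_cap_from_denominator(self):
        schema = make_plain_schema(10)  # 11 required; 10/11 = 0.909 >= 0.8
        a = Assessment(schema=schema, demographics=make_demographics())
        for i in range(10):
            a.set_response(f"item{i:02d}", "Severe Problem")
        result = score_assessment(a)
        assert result.denominator == 10.0
        assert result.score == 1.0
        assert "problems" in result.items_missing

    def test_rounding_half_away_from_zero(self):
        # 14 answered items, one deficit: 1 / (14 + 18) = 1/32 = 0.03125,
        # which must round up to 0.0313 (a bankers' rounder would give 0.0312)
        schema = make_plain_schema(14)
        a = full_assessment(schema, "No Problem", problems=0)
        a.set_response("item00", "Severe Problem")
        assert score_assessment(a).score == 0.0313

    def test_demographics_gate_blocks_scoring(self, schema):
        a = full_assessment(schema)
        a.demographics = dataclasses.replace(a.demographics, healthcare_number="")
        with pytest.raises(ScoreNotComputable, match="healthcare_number"):
            score_assessment(a)


class TestScoreProperties:
    @settings(max_examples=60, deadline=None)
    @given(
        codes=st.lists(st.sampled_from(["No Problem", "Some Problem", "Severe Problem"]),
                       min_size=8, max_size=8),
        problems=st.integers(min_value=0, max_value=30),
    )
    def test_bounds_hold_for_every_complete_form(self, codes, problems):
        schema = make_plain_schema(8)
        a = Assessment(schema=schema, demographics=make_demographics())
        for i, level in enumerate(codes):
            a.set_response(f"item{i:02d}", level)
        a.set_response("problems", problems)
        assert 0.0 <= score_assessment(a).score <= 1.0

    def test_raising_one_item_never_decreases_score(self):
        schema = make_plain_schema(8)
        rng = random.Random(11)
        levels = ["No Problem", "Some Problem", "Severe Problem"]
        for _ in range(20):
            a = full_assessment(schema, rng.choice(levels), problems=rng.randrange(31))
            target = f"item{rng.randrange(8):02d}"
            scores = []
            for level in levels:  # increasing coded value
                a.set_response(target, level)
                scores.append(score_assessment(a).score)
            assert scores == sorted(scores)

    def test_item_order_never_affects_the_score(self):
        schema = make_plain_schema(9)
        rng = random.Random(5)
        a = full_assessment(schema, "Some Problem", problems=4)
        baseline = score_assessment(a).score
        for _ in range(5):
            items = list(schema.items)
            rng.shuffle(items)
            shuffled = schema.with_items(items)
            b = Assessment(schema=shuffled, demographics=make_demographics(),
                           responses=dict(a.responses))
            assert score_assessment(b).score == baseline

    def test_ceiling_saturates_above_cap(self, schema):
        scores = set()
        for raw in range(18, 31):
            a = full_assessment(schema, problems=raw)
            scores.add(score_assessment(a).score)
        assert len(scores) == 1

    def test_below_cap_comorbidity_still_varies_score(self, schema):
        s0 = score_assessment(full_assessment(schema, problems=0)).score
        s9 = score_assessment(full_assessment(schema, problems=9)).score
        assert s9 > s0
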