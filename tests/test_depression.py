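"""The depressive-syndrome cascade: A/B criteria, cascade order, oracle
equivalence and monotonicity."""

import itertools

import pytest

from stagekit import (
    ClinicalFlags,
    DepressionLabel,
    DepressionNotEvaluable,
    OrdinalFlag,
    RunConfig,
    b_features,
    stage_depression,
    symptom_flags,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# independent truth-table oracle: re-derives the cascade from the record
# with none of the implementation's machinery

def oracle_label(qids_items, flags):
    """Re-derive the depressive cascade label from raw QIDS items + flags."""
    v = {i: qids_items.get(i, 0) for i in range(1, 17)}
    total = (
        max(v[1], v[2], v[3], v[4]) + v[5] + max(v[6], v[7], v[8], v[9])
        + v[10] + v[11] + v[12] + v[13] + v[14] + max(v[15], v[16])
    )

    def a_count(thr):
        return sum([
            v[15] >= thr or v[16] >= thr,
            max(v[1], v[2], v[3], v[4]) >= thr,
            v[10] >= thr,
            v[14] >= thr,
        ])

    b_severe = (
        flags.hypomania == OrdinalFlag.PROBABLE
        or flags.psychosis == OrdinalFlag.PROBABLE
        or flags.severe_suicidality
        or flags.comorbidity == OrdinalFlag.PROBABLE
        or flags.substance_misuse == OrdinalFlag.PROBABLE
        or flags.course_flag
    )
    b_moderate = (
        flags.hypomania >= OrdinalFlag.POSSIBLE
        or flags.psychosis >= OrdinalFlag.POSSIBLE
        or flags.severe_suicidality
        or flags.comorbidity >= OrdinalFlag.POSSIBLE
        or flags.substance_misuse >= OrdinalFlag.POSSIBLE
    )
    if total >= 21 and a_count(3) >= 2 and b_severe:
        return DepressionLabel.STAGE_2PLUS_SEVERE
    if total >= 11 and a_count(2) >= 2 and b_moderate:
        return DepressionLabel.STAGE_1B_MODERATE
    return DepressionLabel.STAGE_1A_MILD


class TestSymptomFlags:
    def test_all_zero_record_has_no_flags(self, config):
        rec = make_record(qids_items=[0] * 16)
        assert symptom_flags(rec, "severe", config).count() == 0

    def test_cross_scale_or(self, config):
        # QIDS psychomotor at 3 plus PHQ-9 sleep at 3: two severe flags
        rec = make_record(qids_items={15: 3}, phq9_items={3: 3})
        fs = symptom_flags(rec, "severe", config)
        assert fs.psychomotor and fs.sleep and fs.count() == 2

    def test_moderate_threshold(self, config):
        rec = make_record(qids_items={10: 2})
        assert symptom_flags(rec, "moderate", config).concentration
        assert not symptom_flags(rec, "severe", config).concentration

    def test_no_scale_is_not_evaluable(self, config):
        rec = make_record(flags=ClinicalFlags(course_flag=True))
        with pytest.raises(DepressionNotEvaluable):
            symptom_flags(rec, "severe", config)

    def test_literal_equality_sleep_criterion(self):
        literal = RunConfig.model_validate(
            {"depression": {"literal_equality": True}}
        )
        # a sleep item at 3 is "= 2" false under the printed moderate text
        rec = make_record(qids_items={1: 3})
        assert not symptom_flags(rec, "moderate", literal).sleep
        assert symptom_flags(rec, "moderate", RunConfig()).sleep
        # severe level unaffected: the maximum is 3 either way
        assert symptom_flags(rec, "severe", literal).sleep


class TestBFeatures:
    def test_empty(self):
        assert b_features(ClinicalFlags(), "severe") == []

    def test_probable_psychosis_fires_severe(self):
        fired = b_features(ClinicalFlags(psychosis=OrdinalFlag.PROBABLE), "severe")
        assert fired == ["probable_psychotic_symptoms"]

    def test_possible_substance_fires_moderate_only(self):
        flags = ClinicalFlags(substance_misuse=OrdinalFlag.POSSIBLE)
        assert b_features(flags, "severe") == []
        assert b_features(flags, "moderate") == ["possible_substance_misuse"]

    def test_course_flag_counts_at_severe_level_only(self):
        flags = ClinicalFlags(course_flag=True)
        assert b_features(flags, "severe") == ["illness_course_flag"]
        assert b_features(flags, "moderate") == []

    def test_severe_suicidality_counts_at_both_levels(self):
        flags = ClinicalFlags(severe_suicidality=True)
        assert "severe_suicidality" in b_features(flags, "severe")
        assert "severe_suicidality" in b_features(flags, "moderate")


class TestCascade:
    def test_severe_branch(self, config):
        # total 22 with psychomotor + energy at 3 and probable psychosis
        rec = make_record(
            qids_items={15: 3, 14: 3, 5: 3, 10: 3, 11: 3, 12: 3, 13: 3, 1: 1},
            flags=ClinicalFlags(psychosis=OrdinalFlag.PROBABLE),
        )
        res = stage_depression(rec, config)
        assert res.label == DepressionLabel.STAGE_2PLUS_SEVERE
        assert any("severe_branch" in t and "fired" in t for t in res.trace)

    def test_moderate_branch(self, config):
        # total 12, concentration + energy at 2, possible substance misuse
        rec = make_record(
            qids_items={10: 2, 14: 2, 5: 2, 11: 2, 12: 2, 13: 2},
            flags=ClinicalFlags(substance_misuse=OrdinalFlag.POSSIBLE),
        )
        res = stage_depression(rec, config)
        assert res.label == DepressionLabel.STAGE_1B_MODERATE

    def test_mild_fallthrough(self, config):
        rec = make_record(phq9_items=[1] * 9)  # total 9, below both bands
        res = stage_depression(rec, config)
        assert res.label == DepressionLabel.STAGE_1A_MILD
        # trace records which branch conditions failed
        assert any("severe_branch" in t and "failed" in t for t in res.trace)
        assert any("moderate_branch" in t and "failed" in t for t in res.trace)

    def test_severe_total_without_criteria_falls_to_mild(self, config):
        # total 22 but only one severe A flag and no B feature at any level
        rec = make_record(
            qids_items={15: 3, 5: 3, 10: 2, 11: 3, 12: 3, 13: 3, 14: 2, 1: 2, 6: 1}
        )  # total 22; severe A count 1 (psychomotor only); no B feature
        res = stage_depression(rec, config)
        assert res.label == DepressionLabel.STAGE_1A_MILD

    def test_no_scale_raises(self, config):
        rec = make_record(flags=ClinicalFlags(psychosis=OrdinalFlag.PROBABLE))
        with pytest.raises(DepressionNotEvaluable):
            stage_depression(rec, config)

    def test_determinism(self, config):
        rec = make_record(
            qids_items={15: 3, 14: 3, 5: 3},
            flags=ClinicalFlags(course_flag=True),
        )
        assert stage_depression(rec, config) == stage_depression(rec, config)


class TestOracleEquivalence:
    def test_grid_matches_truth_table(self, config):
        """Exhaustive-ish grid: anchor items x fill levels x B flags."""
        anchor_grid = itertools.product([0, 2, 3], repeat=4)  # items 15,1,10,14
        fills = [0, 2, 3]  # level for the non-A single-item domains
        flag_choices = [
            ClinicalFlags(),
            ClinicalFlags(substance_misuse=OrdinalFlag.POSSIBLE),
            ClinicalFlags(psychosis=OrdinalFlag.PROBABLE),
            ClinicalFlags(course_flag=True),
            ClinicalFlags(severe_suicidality=True),
        ]
        checked = 0
        for (i15, i1, i10, i14), fill, flags in itertools.product(
            anchor_grid, fills, flag_choices
        ):
            items = {15: i15, 1: i1, 10: i10, 14: i14,
                     5: fill, 6: fill, 11: fill, 12: fill, 13: fill}
            rec = make_record(qids_items=items, flags=flags)
            assert stage_depression(rec, config).label == oracle_label(items, flags)
            checked += 1
        assert checked == 81 * 3 * 5
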