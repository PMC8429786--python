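"""The transdiagnostic cascade, ratchet, scheduling, reviews, concordance."""

import datetime as dt
import itertools

import pytest

from stagekit import (
    AssessmentRecord,
    ClinicalFlags,
    CriterionBundle,
    DepressionLabel,
    DepressionResult,
    FunctioningBand,
    OrdinalFlag,
    RunConfig,
    StageHistory,
    StageLabel,
    StagingResult,
    apply_stage_ratchet,
    assign_stage,
    concordance_report,
    ratchet_trajectory,
    record_review,
    schedule_review,
    stage_record,
)
from stagekit.staging import EmptyHistoryError, EmptyReportError

from conftest import OCCASION, make_record


def bundle(functioning, dep=None, **flag_kwargs) -> CriterionBundle:
    depression = (
        None
        if dep is None
        else DepressionResult(label=dep, trace=("oracle-fixture",))
    )
    return CriterionBundle(
        functioning=functioning,
        depression=depression,
        flags=ClinicalFlags(**flag_kwargs),
    )


def oracle_stage(functioning, dep, flags: ClinicalFlags) -> StageLabel:
    """Independent truth table for the primary cascade."""
    two_plus = (
        flags.manic_syndrome
        or flags.psychotic_syndrome
        or dep == DepressionLabel.STAGE_2PLUS_SEVERE
        or flags.severe_anxiety_syndrome
        or flags.hospitalization_history
        or flags.comorbidity == OrdinalFlag.PROBABLE
    )
    one_b = (
        flags.specific_severe_anxiety
        or (dep is not None and dep >= DepressionLabel.STAGE_1B_MODERATE)
        or flags.hypomania >= OrdinalFlag.POSSIBLE
        or flags.psychosis >= OrdinalFlag.POSSIBLE
        or flags.comorbidity >= OrdinalFlag.POSSIBLE
        or flags.substance_misuse >= OrdinalFlag.POSSIBLE
    )
    if functioning == FunctioningBand.MAJOR_ONGOING and two_plus:
        return StageLabel.STAGE_2_PLUS
    if functioning >= FunctioningBand.MODERATE_SEVERE and one_b:
        return StageLabel.STAGE_1B
    return StageLabel.STAGE_1A


class TestAssignStage:
    def test_major_functioning_plus_psychotic_syndrome(self, config):
        res = assign_stage(bundle(FunctioningBand.MAJOR_ONGOING, psychotic_syndrome=True), config)
        assert res.stage == StageLabel.STAGE_2_PLUS
        assert any("clear_psychotic_syndrome" in c for c in res.fired_criteria)
        assert any("functioning" in c for c in res.fired_criteria)

    def test_moderate_functioning_plus_moderate_depression(self, config):
        res = assign_stage(
            bundle(FunctioningBand.MODERATE_SEVERE, dep=DepressionLabel.STAGE_1B_MODERATE),
            config,
        )
        assert res.stage == StageLabel.STAGE_1B

    def test_no_impairment_no_flags(self, config):
        res = assign_stage(bundle(FunctioningBand.NONE_MILD), config)
        assert res.stage == StageLabel.STAGE_1A

    def test_major_impairment_without_syndrome_is_1a_with_warning(self, config):
        res = assign_stage(bundle(FunctioningBand.MAJOR_ONGOING), config)
        assert res.stage == StageLabel.STAGE_1A
        assert any("without any listed syndrome" in w for w in res.warnings)

    def test_2plus_branch_evaluated_before_1b(self, config):
        # satisfies both branches: the cascade must stop at 2+
        res = assign_stage(
            bundle(
                FunctioningBand.MAJOR_ONGOING,
                dep=DepressionLabel.STAGE_1B_MODERATE,
                psychotic_syndrome=True,
                substance_misuse=OrdinalFlag.POSSIBLE,
            ),
            config,
        )
        assert res.stage == StageLabel.STAGE_2_PLUS

    def test_severe_depression_below_major_functioning_is_1b(self, config):
        # default reading: a severe depressive syndrome with sub-major
        # functioning still satisfies the 1b depressive criterion
        res = assign_stage(
            bundle(FunctioningBand.MODERATE_SEVERE, dep=DepressionLabel.STAGE_2PLUS_SEVERE),
            config,
        )
        assert res.stage == StageLabel.STAGE_1B

    def test_literal_reading_drops_severe_depression_to_1a(self):
        literal = RunConfig.model_validate(
            {"staging": {"count_severe_depression_for_1b": False}}
        )
        res = assign_stage(
            bundle(FunctioningBand.MODERATE_SEVERE, dep=DepressionLabel.STAGE_2PLUS_SEVERE),
            literal,
        )
        assert res.stage == StageLabel.STAGE_1A

    def test_major_functioning_satisfies_moderate_requirement(self, config):
        # ordered bands: major impact + a 1b-only syndrome -> stage 1b
        res = assign_stage(
            bundle(FunctioningBand.MAJOR_ONGOING, substance_misuse=OrdinalFlag.POSSIBLE),
            config,
        )
        assert res.stage == StageLabel.STAGE_1B

    def test_not_evaluable_depression_still_triages(self, config):
        res = assign_stage(bundle(FunctioningBand.MAJOR_ONGOING, dep=None, manic_syndrome=True), config)
        assert res.stage == StageLabel.STAGE_2_PLUS

    def test_2plus_result_traces_functioning_and_syndrome(self, config):
        res = assign_stage(bundle(FunctioningBand.MAJOR_ONGOING, hospitalization_history=True), config)
        fired = list(res.fired_criteria)
        assert "functioning:major_ongoing_impact" in fired
        assert any(c.startswith("2+:") for c in fired)

    def test_oracle_equivalence_full_grid(self, config):
        """Truth-table equivalence over the full criterion grid."""
        deps = [None, *DepressionLabel]
        bools = [False, True]
        ords = list(OrdinalFlag)
        n = 0
        for func, dep, manic, psych_syn, anx, spec_anx, hosp, com, sub, hyp, psy in itertools.product(
            FunctioningBand, deps, bools, bools, bools, bools, bools, ords, ords, ords, ords
        ):
            flags = ClinicalFlags(
                manic_syndrome=manic, psychotic_syndrome=psych_syn,
                severe_anxiety_syndrome=anx, specific_severe_anxiety=spec_anx,
                hospitalization_history=hosp, comorbidity=com,
                substance_misuse=sub, hypomania=hyp, psychosis=psy,
            )
            b = CriterionBundle(
                functioning=func,
                depression=None if dep is None else DepressionResult(label=dep, trace=()),
                flags=flags,
            )
            assert assign_stage(b, config).stage == oracle_stage(func, dep, flags)
            n += 1
        assert n == 3 * 4 * 2 ** 5 * 3 ** 4


class TestStageRecord:
    def test_all_zero_record(self, config):
        rec = make_record(qids_items=[0] * 16, phq9_items=[0] * 9)
        assert stage_record(rec, config).stage == StageLabel.STAGE_1A

    def test_composed_severe_example(self, config):
        rec = make_record(
            qids_items={15: 3, 14: 3, 5: 3, 10: 3, 11: 3, 12: 3, 13: 3, 1: 1},
            flags=ClinicalFlags(psychosis=OrdinalFlag.PROBABLE),
            functioning=FunctioningBand.MAJOR_ONGOING,
        )
        res = stage_record(rec, config)
        assert res.stage == StageLabel.STAGE_2_PLUS
        # secondary-cascade trace is attached for audit
        assert any(c.startswith("depression|") for c in res.fired_criteria)

    def test_functioning_score_mapped_via_config_edges(self, config):
        from stagekit import Functioning

        rec = make_record(
            qids_items=[0] * 16,
            flags=ClinicalFlags(substance_misuse=OrdinalFlag.POSSIBLE),
            functioning=Functioning(score=60.0),  # 51-70 -> moderate_severe
        )
        assert stage_record(rec, config).stage == StageLabel.STAGE_1B

    def test_no_depression_scale_warns_but_stages(self, config):
        rec = make_record(
            flags=ClinicalFlags(manic_syndrome=True),
            functioning=FunctioningBand.MAJOR_ONGOING,
        )
        res = stage_record(rec, config)
        assert res.stage == StageLabel.STAGE_2_PLUS
        assert any("not evaluable" in w for w in res.warnings)


def history(stages, person_id="h1") -> StageHistory:
    results = [
        StagingResult(
            person_id=person_id,
            occasion=OCCASION + dt.timedelta(days=30 * i),
            stage=s,
        )
        for i, s in enumerate(stages)
    ]
    return StageHistory(person_id=person_id, results=results)


class TestRatchet:
    def test_never_moves_back(self):
        h = history([StageLabel.STAGE_2_PLUS, StageLabel.STAGE_1B])
        assert apply_stage_ratchet(h) == StageLabel.STAGE_2_PLUS

    def test_singleton(self):
        assert apply_stage_ratchet(history([StageLabel.STAGE_1A])) == StageLabel.STAGE_1A

    def test_empty_history_rejected(self):
        with pytest.raises(EmptyHistoryError):
            apply_stage_ratchet(StageHistory(person_id="x"))

    def test_permutation_invariance(self):
        base = [StageLabel.STAGE_1A, StageLabel.STAGE_1A, StageLabel.STAGE_1B,
                StageLabel.STAGE_2_PLUS, StageLabel.STAGE_1B]
        outputs = {
            apply_stage_ratchet(history(list(p))) for p in itertools.permutations(base)
        }
        assert outputs == {StageLabel.STAGE_2_PLUS}

    def test_idempotent_under_self_extension(self):
        h = history([StageLabel.STAGE_1B, StageLabel.STAGE_1A])
        out = apply_stage_ratchet(h)
        h.append(
            StagingResult(person_id="h1", occasion=OCCASION + dt.timedelta(days=999), stage=out)
        )
        assert apply_stage_ratchet(h) == out

    def test_trajectory_is_running_max(self):
        h = history([StageLabel.STAGE_1B, StageLabel.STAGE_1A, StageLabel.STAGE_2_PLUS,
                     StageLabel.STAGE_1A])
        assert ratchet_trajectory(h) == [
            StageLabel.STAGE_1B, StageLabel.STAGE_1B,
            StageLabel.STAGE_2_PLUS, StageLabel.STAGE_2_PLUS,
        ]


class TestScheduling:
    def test_1b_reviewed_after_one_month(self, config):
        assert schedule_review(StageLabel.STAGE_1B, config) == 30

    def test_intervals_strictly_decrease_with_severity(self, config):
        days = [schedule_review(s, config) for s in StageLabel]
        assert days[0] > days[1] > days[2]

    def test_config_override(self):
        cfg = RunConfig.model_validate({"review_intervals": {"stage_1b": 21}})
        assert schedule_review(StageLabel.STAGE_1B, cfg) == 21

    def test_non_decreasing_intervals_rejected_at_load(self):
        with pytest.raises(ValueError):
            RunConfig.model_validate(
                {"review_intervals": {"stage_1a": 10, "stage_1b": 30}}
            )


class TestReviewsAndConcordance:
    def test_agreement_and_referral(self):
        h = StageHistory(person_id="r1")
        e1 = record_review(h, StageLabel.STAGE_1B, StageLabel.STAGE_1B)
        assert e1.agrees and not e1.mdt_referral
        e2 = record_review(h, StageLabel.STAGE_1B, StageLabel.STAGE_2_PLUS)
        assert not e2.agrees and e2.mdt_referral
        assert len(h.clinician_reviews) == 2

    def test_counting_fixture(self):
        h = StageHistory(person_id="r2")
        record_review(h, StageLabel.STAGE_1A, StageLabel.STAGE_1A)
        record_review(h, StageLabel.STAGE_1A, StageLabel.STAGE_1B)
        rep = concordance_report([h])
        assert rep.n_entries == 2
        assert rep.referral_count == 1
        assert rep.agreement_rate == pytest.approx(0.5)

    def test_three_of_four_agree(self):
        hs = []
        pairs = [("1a", "1a"), ("1b", "1b"), ("2+", "2+"), ("1b", "2+")]
        for i, (p, c) in enumerate(pairs):
            h = StageHistory(person_id=f"r{i}")
            record_review(h, StageLabel.parse(p), StageLabel.parse(c))
            hs.append(h)
        rep = concordance_report(hs)
        assert rep.agreement_rate == pytest.approx(0.75)
        assert rep.confusion.loc["1b", "2+"] == 1
        # marginals conserve the entry count
        assert rep.confusion.to_numpy().sum() == rep.n_entries

    def test_all_agree_is_diagonal(self):
        hs = []
        for i, s in enumerate(StageLabel):
            h = StageHistory(person_id=f"d{i}")
            record_review(h, s, s)
            hs.append(h)
        rep = concordance_report(hs)
        assert rep.agreement_rate == 1.0
        off_diag = rep.confusion.to_numpy().sum() - sum(
            rep.confusion.loc[s.code, s.code] for s in StageLabel
        )
        assert off_diag == 0

    def test_empty_report_rejected(self):
        with pytest.raises(EmptyReportError):
            concordance_report([StageHistory(person_id="x")])
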