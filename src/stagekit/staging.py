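"""The transdiagnostic staging cascade, stage ratchet, review scheduling
and clinician-concordance audit.

The primary cascade assigns one of three ordered stages from a resolved
criterion bundle (functioning band, depressive-syndrome result, clinical
flags):

* **Stage 2+** — functioning shows ongoing and *major* impact AND at least
  one full-threshold syndrome: clear manic or psychotic syndrome, a clear
  severe depressive syndrome (from the secondary cascade), a clear severe
  anxiety syndrome, previous psychiatric hospitalization, or significant
  and ongoing (probable) comorbidity.
* **Stage 1b** — failing that, functioning shows at least
  *moderate-to-severe* impact AND at least one attenuated syndrome: a
  specific more-severe anxiety syndrome, a moderate depression syndrome,
  hypomanic or attenuated psychotic symptoms (possible-or-above), or
  significant (possible-or-above) comorbidity or substance misuse.
* **Stage 1a** — otherwise.

The cascade always yields a stage: a record without any depression scale
simply contributes no depressive criteria (with a warning), because triage
cannot refuse to answer. Once assigned, stages only ratchet upward over a
person's history — remission never moves someone back to an earlier stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import RunConfig
from .depression import DepressionNotEvaluable, stage_depression
from .models import (
    AssessmentRecord,
    ClinicalFlags,
    DepressionLabel,
    DepressionResult,
    FunctioningBand,
    ReviewEntry,
    StageHistory,
    StageLabel,
    StagingResult,
)


class EmptyHistoryError(ValueError):
    pass


class EmptyReportError(ValueError):
    pass


@dataclass(frozen=True)
class CriterionBundle:
    """Resolved inputs the primary cascade consumes, from one record."""

    functioning: FunctioningBand
    depression: Optional[DepressionResult]  # None = not evaluable
    flags: ClinicalFlags
    warnings: tuple[str, ...] = ()


def build_bundle(record: AssessmentRecord, config: RunConfig) -> CriterionBundle:
    """Resolve one assessment record into a criterion bundle.

    Scores the scales and runs the depressive-syndrome cascade; resolves a
    functioning score into a band via the configured edges when no band was
    given directly.
    """
    warnings: list[str] = []
    if record.functioning.band is not None:
        functioning = record.functioning.band
    elif record.functioning.score is not None:
        functioning = config.functioning.band_for_score(record.functioning.score)
    else:
        functioning = FunctioningBand.NONE_MILD
        warnings.append("no functioning rating: assumed none_mild")

    depression: Optional[DepressionResult]
    try:
        depression = stage_depression(record, config)
        warnings += [t for t in depression.trace if t.startswith("warning:")]
    except DepressionNotEvaluable:
        depression = None
        warnings.append("depression not evaluable: no depression scale present")

    return CriterionBundle(
        functioning=functioning,
        depression=depression,
        flags=record.flags,
        warnings=tuple(warnings),
    )


def assign_stage(
    bundle: CriterionBundle,
    config: RunConfig | None = None,
    *,
    person_id: str = "",
    occasion=None,
) -> StagingResult:
    """Run the primary cascade on a resolved criterion bundle."""
    import datetime as _dt

    config = config or RunConfig()
    occasion = occasion or _dt.date(1970, 1, 1)
    flags = bundle.flags
    st = config.staging
    fired: list[str] = []
    warnings = list(bundle.warnings)

    dep_label = bundle.depression.label if bundle.depression is not None else None

    fired.append(f"functioning={bundle.functioning.name.lower()}")

    # ---- stage 2+ branch -------------------------------------------------
    syndromes_2plus = [
        ("clear_manic_syndrome", flags.manic_syndrome),
        ("clear_psychotic_syndrome", flags.psychotic_syndrome),
        (
            "clear_severe_depressive_syndrome",
            dep_label == DepressionLabel.STAGE_2PLUS_SEVERE,
        ),
        ("clear_severe_anxiety_syndrome", flags.severe_anxiety_syndrome),
        ("previous_hospitalization", flags.hospitalization_history),
        (
            "significant_ongoing_comorbidity",
            flags.comorbidity >= st.comorbidity_2plus,
        ),
    ]
    major = bundle.functioning >= FunctioningBand.MAJOR_ONGOING
    hits_2plus = [name for name, hit in syndromes_2plus if hit]
    if major and hits_2plus:
        fired += ["functioning:major_ongoing_impact"] + [
            f"2+:{n}" for n in hits_2plus
        ]
        return StagingResult(
            person_id=person_id, occasion=occasion,
            stage=StageLabel.STAGE_2_PLUS,
            fired_criteria=tuple(fired), warnings=tuple(warnings),
        )

    # ---- stage 1b branch -------------------------------------------------
    syndromes_1b = [
        ("specific_severe_anxiety_syndrome", flags.specific_severe_anxiety),
        (
            "moderate_depression_syndrome",
            dep_label == DepressionLabel.STAGE_1B_MODERATE
            or (
                st.count_severe_depression_for_1b
                and dep_label == DepressionLabel.STAGE_2PLUS_SEVERE
            ),
        ),
        (
            "hypomanic_or_attenuated_psychotic_symptoms",
            flags.hypomania >= st.hypomania_1b or flags.psychosis >= st.psychosis_1b,
        ),
        (
            "significant_comorbidity_or_substance_misuse",
            flags.comorbidity >= st.comorbidity_1b
            or flags.substance_misuse >= st.substance_1b,
        ),
    ]
    moderate = bundle.functioning >= FunctioningBand.MODERATE_SEVERE
    hits_1b = [name for name, hit in syndromes_1b if hit]
    if moderate and hits_1b:
        fired += ["functioning:moderate_to_severe_impact"] + [
            f"1b:{n}" for n in hits_1b
        ]
        return StagingResult(
            person_id=person_id, occasion=occasion,
            stage=StageLabel.STAGE_1B,
            fired_criteria=tuple(fired), warnings=tuple(warnings),
        )

    # ---- stage 1a --------------------------------------------------------
    if major and not hits_2plus and not hits_1b:
        # literal-cascade corner: major impairment but no listed syndrome
        warnings.append(
            "major functional impairment without any listed syndrome: "
            "assigned 1a by the literal cascade; clinical review advised"
        )
    if not major and hits_2plus:
        fired.append("1a:2plus_syndromes_present_but_functioning_below_major")
    if not moderate and hits_1b:
        fired.append("1a:1b_syndromes_present_but_functioning_below_moderate")
    if (major or moderate) and not hits_2plus and not hits_1b:
        fired.append("1a:functioning_impact_without_qualifying_syndrome")
    if not fired[1:]:
        fired.append("1a:no_branch_condition_met")
    return StagingResult(
        person_id=person_id, occasion=occasion,
        stage=StageLabel.STAGE_1A,
        fired_criteria=tuple(fired), warnings=tuple(warnings),
    )


def stage_record(record: AssessmentRecord, config: RunConfig | None = None) -> StagingResult:
    """Full pipeline for one record: score scales, run both cascades."""
    config = config or RunConfig()
    bundle = build_bundle(record, config)
    result = assign_stage(
        bundle, config, person_id=record.person_id, occasion=record.occasion
    )
    if bundle.depression is not None:
        # attach the secondary-cascade trace for auditability
        result = result.model_copy(
            update={
                "fired_criteria": result.fired_criteria
                + tuple(f"depression|{t}" for t in bundle.depression.trace)
            }
        )
    return result


def stage_records(
    records: Iterable[AssessmentRecord], config: RunConfig | None = None
) -> list[StagingResult]:
    config = config or RunConfig()
    return [stage_record(r, config) for r in records]


def apply_stage_ratchet(history: StageHistory) -> StageLabel:
    """Current stage under the ratchet: the maximum stage ever assigned.

    A person placed on the staging continuum never moves back to an
    earlier stage, even in remission.
    """
    if not history.results:
        raise EmptyHistoryError(f"no staging results for {history.person_id!r}")
    return max(r.stage for r in history.results)


def ratchet_trajectory(history: StageHistory) -> list[StageLabel]:
    """Running-maximum stage at each occasion (non-decreasing by design)."""
    out: list[StageLabel] = []
    current = StageLabel.STAGE_1A
    for r in history.results:
        current = max(current, r.stage)
        out.append(current)
    return out


def schedule_review(current: StageLabel, config: RunConfig | None = None) -> int:
    """Days until the next scheduled stage review.

    Later stages are reviewed more frequently; stage 1b defaults to the
    1-month (30-day) interval.
    """
    config = config or RunConfig()
    return config.review_intervals.for_stage(current)


def record_review(
    history: StageHistory,
    protocol_stage: StageLabel,
    clinician_stage: StageLabel,
    occasion=None,
) -> ReviewEntry:
    """Append a clinician review; disagreement triggers an MDT referral."""
    import datetime as _dt

    if occasion is None:
        occasion = (
            history.results[-1].occasion if history.results else _dt.date(1970, 1, 1)
        )
    entry = ReviewEntry(
        occasion=occasion,
        protocol_stage=StageLabel.parse(protocol_stage),
        clinician_stage=StageLabel.parse(clinician_stage),
    )
    history.clinician_reviews.append(entry)
    return entry


@dataclass(frozen=True)
class ConcordanceReport:
    """Protocol-vs-clinician agreement summary across histories."""

    n_entries: int
    agreement_rate: float
    confusion: pd.DataFrame = field(compare=False)  # rows: protocol, cols: clinician
    referral_count: int


def concordance_report(histories: Sequence[StageHistory]) -> ConcordanceReport:
    """Summarize clinician concordance: agreement rate, 3x3 confusion
    table (rows = protocol stage, columns = clinician stage), MDT referral
    count."""
    entries = [e for h in histories for e in h.clinician_reviews]
    if not entries:
        raise EmptyReportError("no clinician review entries to report on")
    labels = [s.code for s in StageLabel]
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    confusion.index.name = "protocol"
    confusion.columns.name = "clinician"
    agree = 0
    referrals = 0
    for e in entries:
        confusion.loc[e.protocol_stage.code, e.clinician_stage.code] += 1
        agree += e.agrees
        referrals += e.mdt_referral
    return ConcordanceReport(
        n_entries=len(entries),
        agreement_rate=agree / len(entries),
        confusion=confusion,
        referral_count=referrals,
    )
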