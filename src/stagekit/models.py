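"""Domain types for assessment records and staging results.

The central object is :class:`AssessmentRecord`: one person-occasion bundle
of self-report scale responses (QIDS-SR16 and/or PHQ-9 item answers on a
0-3 Likert scale), a social/occupational functioning rating, and a set of
pre-resolved clinical flags (hypomania, psychosis, suicidality, comorbidity,
substance misuse, hospitalization and illness-course indicators).

Ordered severities are modelled as ``IntEnum`` so that comparisons such as
``flag >= OrdinalFlag.POSSIBLE`` and ``StageLabel`` monotonicity checks read
naturally.
"""

from __future__ import annotations

import datetime as _dt
import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class OrdinalFlag(enum.IntEnum):
    """Three-level clinical screen outcome: none < possible < probable."""

    NONE = 0
    POSSIBLE = 1
    PROBABLE = 2

    @classmethod
    def parse(cls, value) -> "OrdinalFlag":
        if isinstance(value, cls):
            return value
        if isinstance(value, bool):
            return cls.PROBABLE if value else cls.NONE
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return cls(int(value))
        s = str(value).strip().lower()
        if s in ("", "none", "no", "0", "false"):
            return cls.NONE
        if s in ("possible", "1"):
            return cls.POSSIBLE
        if s in ("probable", "2", "true", "yes"):
            return cls.PROBABLE
        raise ValueError(f"cannot parse ordinal flag from {value!r}")


class SeverityBand(enum.IntEnum):
    """Banded scale severity: none/mild < moderate < severe."""

    NONE_MILD = 0
    MODERATE = 1
    SEVERE = 2


class FunctioningBand(enum.IntEnum):
    """Social and occupational functioning impact band (higher = worse)."""

    NONE_MILD = 0
    MODERATE_SEVERE = 1
    MAJOR_ONGOING = 2

    @classmethod
    def parse(cls, value) -> "FunctioningBand":
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return cls(int(value))
        s = str(value).strip().lower()
        aliases = {
            "none_mild": cls.NONE_MILD,
            "none": cls.NONE_MILD,
            "mild": cls.NONE_MILD,
            "moderate_severe": cls.MODERATE_SEVERE,
            "moderate": cls.MODERATE_SEVERE,
            "major_ongoing": cls.MAJOR_ONGOING,
            "major": cls.MAJOR_ONGOING,
        }
        if s in aliases:
            return aliases[s]
        raise ValueError(f"cannot parse functioning band from {value!r}")


class StageLabel(enum.IntEnum):
    """Transdiagnostic clinical stage, ordered 1a < 1b < 2+.

    The engine deliberately collapses stages 2-4 into a single "2+" label:
    the triage decision it supports is low-intensity (1a) vs attenuated
    syndrome (1b) vs full-threshold disorder (2+).
    """

    STAGE_1A = 0
    STAGE_1B = 1
    STAGE_2_PLUS = 2

    @property
    def code(self) -> str:
        return {0: "1a", 1: "1b", 2: "2+"}[int(self)]

    @classmethod
    def parse(cls, value) -> "StageLabel":
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return cls(int(value))
        s = str(value).strip().lower()
        aliases = {
            "1a": cls.STAGE_1A, "stage_1a": cls.STAGE_1A, "stage 1a": cls.STAGE_1A,
            "1b": cls.STAGE_1B, "stage_1b": cls.STAGE_1B, "stage 1b": cls.STAGE_1B,
            "2+": cls.STAGE_2_PLUS, "stage_2_plus": cls.STAGE_2_PLUS,
            "stage 2+": cls.STAGE_2_PLUS, "2plus": cls.STAGE_2_PLUS,
        }
        if s in aliases:
            return aliases[s]
        raise ValueError(f"cannot parse stage label from {value!r}")


class DepressionLabel(enum.IntEnum):
    """Outcome of the depressive-syndrome secondary algorithm."""

    STAGE_1A_MILD = 0
    STAGE_1B_MODERATE = 1
    STAGE_2PLUS_SEVERE = 2


class ScaleId(str, enum.Enum):
    QIDS_SR16 = "QIDS_SR16"
    PHQ9 = "PHQ9"


class ItemResponse(BaseModel):
    """A single Likert item answer; 0 means no impairment, 3 the worst."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    value: int = Field(ge=0, le=3)


class ScaleResponse(BaseModel):
    """Item-level answers for one instrument.

    ``items`` maps 1-based item number to the answered value; unanswered
    items are simply absent. ``completeness`` is the answered fraction.
    """

    model_config = ConfigDict(frozen=True)

    scale_id: ScaleId
    items: dict[int, int]

    @field_validator("items")
    @classmethod
    def _items_in_range(cls, v: dict[int, int]) -> dict[int, int]:
        for k, val in v.items():
            if not 0 <= val <= 3:
                raise ValueError(f"item {k} value {val} outside 0-3")
            if k < 1:
                raise ValueError(f"item number {k} must be >= 1")
        return v

    @model_validator(mode="after")
    def _items_fit_scale(self) -> "ScaleResponse":
        n = {ScaleId.QIDS_SR16: 16, ScaleId.PHQ9: 9}[self.scale_id]
        bad = [k for k in self.items if k > n]
        if bad:
            raise ValueError(f"{self.scale_id.value} has no item(s) {bad}")
        return self

    @property
    def n_items(self) -> int:
        return {ScaleId.QIDS_SR16: 16, ScaleId.PHQ9: 9}[self.scale_id]

    @property
    def completeness(self) -> float:
        return len(self.items) / self.n_items

    def item(self, number: int, default: int = 0) -> int:
        return self.items.get(number, default)

    def item_responses(self) -> list[ItemResponse]:
        prefix = "qids" if self.scale_id is ScaleId.QIDS_SR16 else "phq9"
        return [
            ItemResponse(item_id=f"{prefix}_{k:02d}", value=v)
            for k, v in sorted(self.items.items())
        ]


class ClinicalFlags(BaseModel):
    """Pre-resolved clinical screen outcomes feeding the staging cascades.

    The ordinal screens (hypomania, psychosis, comorbidity, substance
    misuse) arrive already banded none/possible/probable; the engine does
    not invent psychometric cutoffs for them. ``course_flag`` covers early
    onset, a previous severe episode, treatment resistance or recurrence.
    """

    model_config = ConfigDict(frozen=True)

    hypomania: OrdinalFlag = OrdinalFlag.NONE
    psychosis: OrdinalFlag = OrdinalFlag.NONE
    severe_suicidality: bool = False
    comorbidity: OrdinalFlag = OrdinalFlag.NONE
    substance_misuse: OrdinalFlag = OrdinalFlag.NONE
    hospitalization_history: bool = False
    course_flag: bool = False
    manic_syndrome: bool = False
    psychotic_syndrome: bool = False
    severe_anxiety_syndrome: bool = False
    specific_severe_anxiety: bool = False

    def any_set(self) -> bool:
        return any(
            bool(getattr(self, name)) for name in type(self).model_fields
        )


class Functioning(BaseModel):
    """Functioning rating: a band directly, and/or a 0-100 source score.

    When only a score is given the band is resolved against configurable
    edges at staging time (lower scores = worse functioning).
    """

    model_config = ConfigDict(frozen=True)

    band: Optional[FunctioningBand] = None
    score: Optional[float] = Field(default=None, ge=0, le=100)

    @model_validator(mode="after")
    def _something_given(self) -> "Functioning":
        # both None is legal: staging treats it as none_mild with a warning
        return self


class AssessmentRecord(BaseModel):
    """One person-occasion bundle of scales, flags and functioning."""

    model_config = ConfigDict(frozen=True)

    person_id: str
    occasion: _dt.date
    scales: tuple[ScaleResponse, ...] = ()
    flags: ClinicalFlags = ClinicalFlags()
    functioning: Functioning = Functioning()

    @model_validator(mode="after")
    def _not_empty(self) -> "AssessmentRecord":
        if not self.scales and not self.flags.any_set() and self.functioning.band is None and self.functioning.score is None:
            raise ValueError(
                "empty assessment: no scale responses, no flags, no functioning"
            )
        seen: set[ScaleId] = set()
        for s in self.scales:
            if s.scale_id in seen:
                raise ValueError(f"duplicate scale {s.scale_id.value}")
            seen.add(s.scale_id)
        return self

    def scale(self, scale_id: ScaleId) -> Optional[ScaleResponse]:
        for s in self.scales:
            if s.scale_id is scale_id:
                return s
        return None


class DepressionResult(BaseModel):
    """Label plus a criterion-by-criterion trace of the depressive cascade."""

    model_config = ConfigDict(frozen=True)

    label: DepressionLabel
    trace: tuple[str, ...]


class StagingResult(BaseModel):
    """Assigned stage with the full list of fired criteria and warnings."""

    model_config = ConfigDict(frozen=True)

    person_id: str
    occasion: _dt.date
    stage: StageLabel
    fired_criteria: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


class ReviewEntry(BaseModel):
    """A clinician's stage rating set against the protocol's suggestion.

    Disagreement triggers a multidisciplinary-team (MDT) referral.
    """

    model_config = ConfigDict(frozen=True)

    occasion: _dt.date
    protocol_stage: StageLabel
    clinician_stage: StageLabel

    @property
    def agrees(self) -> bool:
        return self.protocol_stage == self.clinician_stage

    @property
    def mdt_referral(self) -> bool:
        return not self.agrees


class StageHistory(BaseModel):
    """Time-ordered staging results for one person.

    Supports the stage ratchet (a person never moves back to an earlier
    stage, even in remission) and review scheduling.
    """

    person_id: str
    results: list[StagingResult] = Field(default_factory=list)
    clinician_reviews: list[ReviewEntry] = Field(default_factory=list)

    @model_validator(mode="after")
    def _ordered(self) -> "StageHistory":
        occasions = [r.occasion for r in self.results]
        if any(b < a for a, b in zip(occasions, occasions[1:])):
            raise ValueError("staging results must be time-ordered")
        return self

    def append(self, result: StagingResult) -> None:
        if self.results and result.occasion < self.results[-1].occasion:
            raise ValueError("out-of-order occasion")
        self.results.append(result)
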