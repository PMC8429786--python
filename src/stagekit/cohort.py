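"""Seeded synthetic assessment cohorts with controllable latent stage.

No real intake data ships with this package; every branch of the staging
cascades is exercised on synthetic cohorts instead. Each simulated person
draws a latent stage from a mixture, and a noise-free record for that
stage is constructed *from the configured thresholds* so that it satisfies
exactly its stage's criteria:

* 2+ template — major functioning impact, a depression total at or above
  the severe cutoff, two severe A-criterion items at the severe threshold,
  one severe B feature;
* 1b template — moderate-to-severe functioning, a total in the moderate
  band, two moderate A items, one moderate B feature (no severe features);
* 1a template — mild functioning, sub-threshold totals, all items below
  the moderate item threshold, no flags.

Noise then perturbs this template: each item is independently resampled
uniformly on 0-3 with probability ``noise`` and each flag is independently
resampled/toggled with the same probability. At ``noise=0`` the engine
recovers the latent stage perfectly — that recovery property is the
module's defining contract; as noise grows toward 0.5 the records carry
less and less stage signal. The generator is a test-fixture factory, not
an epidemiological population model: items within a record are perturbed
independently, with none of the item correlation structure of real
questionnaire data.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import RunConfig
from .models import (
    AssessmentRecord,
    ClinicalFlags,
    Functioning,
    FunctioningBand,
    OrdinalFlag,
    ScaleId,
    ScaleResponse,
    StageHistory,
    StageLabel,
)
from .scales import definition

_BASE_DATE = _dt.date(2024, 1, 8)


class CohortSpec(BaseModel):
    """Parameters of a synthetic cohort draw."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(gt=0)
    seed: int = 0
    stage_mixture: tuple[float, float, float] = (0.5, 0.3, 0.2)  # P(1a), P(1b), P(2+)
    noise: float = Field(default=0.0, ge=0.0, le=1.0)
    occasions: int = Field(default=1, ge=1)
    # probability that a latent stage steps down (remits) / up (progresses)
    # between consecutive occasions; the remainder stays put
    drift_down: float = 0.25
    drift_up: float = 0.15

    @model_validator(mode="after")
    def _valid_mixture(self) -> "CohortSpec":
        if any(p < 0 for p in self.stage_mixture):
            raise ValueError("mixture probabilities must be non-negative")
        if abs(sum(self.stage_mixture) - 1.0) > 1e-9:
            raise ValueError(f"stage mixture must sum to 1, got {sum(self.stage_mixture)}")
        if self.drift_down + self.drift_up > 1.0:
            raise ValueError("drift probabilities must sum to <= 1")
        return self


@dataclass
class Cohort:
    """Generated records plus the latent truth they were built from."""

    records: list[AssessmentRecord]
    latent_stages: list[StageLabel]
    spec: CohortSpec = field(repr=False, default=None)


def _distribute(rng: np.random.Generator, amount: int, n_slots: int, cap: int) -> list[int]:
    """Randomly distribute ``amount`` points over ``n_slots`` slots, each <= cap."""
    slots = [0] * n_slots
    order = rng.permutation(n_slots)
    remaining = amount
    for j, idx in enumerate(order):
        hi = min(cap, remaining)
        lo = max(0, remaining - cap * (n_slots - j - 1))
        v = int(rng.integers(lo, hi + 1))
        slots[idx] = v
        remaining -= v
    assert remaining == 0
    return slots


def _qids_items(rng, total: int, fixed: dict[int, int]) -> dict[int, int]:
    """QIDS item vector whose domain-max total equals ``total``.

    ``fixed`` pins specific items (the A-criterion symptoms); remaining
    single-item domains absorb the remainder. Multi-item domains not pinned
    are set via their first item so domain-max == item value.
    """
    d = definition(ScaleId.QIDS_SR16)
    items = dict(fixed)
    fixed_domains = []
    free_domains = []
    for dom in d.domains:
        if any(i in fixed for i in dom):
            fixed_domains.append(dom)
        else:
            free_domains.append(dom)
    base = sum(max(items.get(i, 0) for i in dom) for dom in fixed_domains)
    remainder = total - base
    if not 0 <= remainder <= 3 * len(free_domains):
        raise ValueError(f"total {total} unreachable with fixed items {fixed}")
    fill = _distribute(rng, remainder, len(free_domains), 3)
    for dom, v in zip(free_domains, fill):
        items[dom[0]] = v
    return items


def _phq9_items(rng, total: int, fixed: dict[int, int]) -> dict[int, int]:
    items = dict(fixed)
    free = [i for i in range(1, 10) if i not in fixed]
    remainder = total - sum(fixed.values())
    if not 0 <= remainder <= 3 * len(free):
        raise ValueError(f"total {total} unreachable with fixed items {fixed}")
    fill = _distribute(rng, remainder, len(free), 3)
    for i, v in zip(free, fill):
        items[i] = v
    return items


def _template_record(
    rng: np.random.Generator,
    stage: StageLabel,
    person_id: str,
    occasion: _dt.date,
    config: RunConfig,
) -> AssessmentRecord:
    """Noise-free record satisfying exactly ``stage``'s criteria."""
    dep = config.depression
    q_cut = config.cutoffs(ScaleId.QIDS_SR16)
    p_cut = config.cutoffs(ScaleId.PHQ9)
    sev, mod = dep.severe_item_threshold, dep.moderate_item_threshold

    if stage is StageLabel.STAGE_2_PLUS:
        # severe total + A: psychomotor(15) & energy(14) at severe threshold
        q_total = int(rng.integers(q_cut.severe, 28))
        q_fixed = {15: sev, 14: sev}
        p_total = int(rng.integers(p_cut.severe, 28))
        p_fixed = {8: sev, 4: sev}
        # one severe B feature
        b_choice = int(rng.integers(0, 3))
        flags = ClinicalFlags(
            psychosis=OrdinalFlag.PROBABLE if b_choice == 0 else OrdinalFlag.NONE,
            hypomania=OrdinalFlag.PROBABLE if b_choice == 1 else OrdinalFlag.NONE,
            course_flag=b_choice == 2,
        )
        functioning = Functioning(band=FunctioningBand.MAJOR_ONGOING)
    elif stage is StageLabel.STAGE_1B:
        # moderate band total; items capped below the severe item threshold
        # so no severe A flag can fire
        cap = sev - 1
        q_hi = min(q_cut.severe - 1, 2 * cap + 7 * cap)  # fixed 2 + 7 free domains
        q_total = int(rng.integers(q_cut.moderate, q_hi + 1))
        q_fixed = {10: mod, 14: mod}
        p_hi = min(p_cut.severe - 1, 2 * mod + 7 * cap)
        p_total = int(rng.integers(p_cut.moderate, p_hi + 1))
        p_fixed = {7: mod, 4: mod}
        flags = ClinicalFlags(
            substance_misuse=OrdinalFlag.POSSIBLE
            if rng.integers(0, 2)
            else OrdinalFlag.NONE,
            comorbidity=OrdinalFlag.NONE,
        )
        if flags.substance_misuse is OrdinalFlag.NONE:
            flags = ClinicalFlags(comorbidity=OrdinalFlag.POSSIBLE)
        functioning = Functioning(band=FunctioningBand.MODERATE_SEVERE)
    else:
        # sub-threshold everywhere: items below the moderate item threshold
        cap = mod - 1
        q_total = int(rng.integers(0, min(q_cut.moderate - 1, 9 * cap) + 1))
        q_fixed = {}
        p_total = int(rng.integers(0, min(p_cut.moderate - 1, 9 * cap) + 1))
        p_fixed = {}
        flags = ClinicalFlags()
        functioning = Functioning(band=FunctioningBand.NONE_MILD)

    cap = 3 if stage is StageLabel.STAGE_2_PLUS else (sev - 1 if stage is StageLabel.STAGE_1B else mod - 1)
    q_items = _qids_items_capped(rng, q_total, q_fixed, cap)
    p_items = _phq9_items_capped(rng, p_total, p_fixed, cap)
    return AssessmentRecord(
        person_id=person_id,
        occasion=occasion,
        scales=(
            ScaleResponse(scale_id=ScaleId.QIDS_SR16, items=q_items),
            ScaleResponse(scale_id=ScaleId.PHQ9, items=p_items),
        ),
        flags=flags,
        functioning=functioning,
    )


def _qids_items_capped(rng, total, fixed, cap):
    d = definition(ScaleId.QIDS_SR16)
    items = dict(fixed)
    free_domains = [dom for dom in d.domains if not any(i in fixed for i in dom)]
    base = sum(
        max(items.get(i, 0) for i in dom) for dom in d.domains if any(i in fixed for i in dom)
    )
    fill = _distribute(rng, total - base, len(free_domains), cap)
    for dom, v in zip(free_domains, fill):
        items[dom[0]] = v
    return {k: v for k, v in items.items()}


def _phq9_items_capped(rng, total, fixed, cap):
    items = dict(fixed)
    free = [i for i in range(1, 10) if i not in fixed]
    fill = _distribute(rng, total - sum(fixed.values()), len(free), cap)
    for i, v in zip(free, fill):
        items[i] = v
    return items


_FLAG_LEVELS = {
    "hypomania": 3, "psychosis": 3, "comorbidity": 3, "substance_misuse": 3,
    "severe_suicidality": 2, "hospitalization_history": 2, "course_flag": 2,
    "manic_syndrome": 2, "psychotic_syndrome": 2,
    "severe_anxiety_syndrome": 2, "specific_severe_anxiety": 2,
}


def _perturb(rng: np.random.Generator, record: AssessmentRecord, noise: float) -> AssessmentRecord:
    if noise == 0:
        return record
    scales = []
    for resp in record.scales:
        items = dict(resp.items)
        for i in range(1, resp.n_items + 1):
            if rng.random() < noise:
                items[i] = int(rng.integers(0, 4))
        scales.append(ScaleResponse(scale_id=resp.scale_id, items=items))
    flag_values = {}
    for name, levels in _FLAG_LEVELS.items():
        v = getattr(record.flags, name)
        if rng.random() < noise:
            drawn = int(rng.integers(0, levels))
            v = OrdinalFlag(drawn) if levels == 3 else bool(drawn)
        flag_values[name] = v
    functioning = record.functioning
    if rng.random() < noise:
        functioning = Functioning(band=FunctioningBand(int(rng.integers(0, 3))))
    return AssessmentRecord(
        person_id=record.person_id,
        occasion=record.occasion,
        scales=tuple(scales),
        flags=ClinicalFlags(**flag_values),
        functioning=functioning,
    )


def generate_cohort(spec: CohortSpec, config: RunConfig | None = None) -> Cohort:
    """Draw a seeded cohort of single-occasion records with latent stages.

    Same spec (including seed) -> identical cohort.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(spec.seed)
    stages = [
        StageLabel(int(s))
        for s in rng.choice(3, size=spec.n, p=list(spec.stage_mixture))
    ]
    records = []
    for k, stage in enumerate(stages):
        rec = _template_record(
            rng, stage, person_id=f"p{k:04d}", occasion=_BASE_DATE, config=config
        )
        records.append(_perturb(rng, rec, spec.noise))
    return Cohort(records=records, latent_stages=stages, spec=spec)


@dataclass
class HistoryFixture:
    """Multi-occasion records for one person plus per-occasion latent stages."""

    person_id: str
    records: list[AssessmentRecord]
    latent_stages: list[StageLabel]


def generate_history(spec: CohortSpec, config: RunConfig | None = None) -> list[HistoryFixture]:
    """Longitudinal fixtures whose latent stage drifts between occasions.

    Downward drift (remission) is included deliberately: raw per-occasion
    stages can decrease, which is exactly what makes ratchet tests
    meaningful.
    """
    if spec.occasions < 2:
        raise ValueError("longitudinal generation needs occasions >= 2")
    config = config or RunConfig()
    rng = np.random.default_rng(spec.seed)
    out = []
    for k in range(spec.n):
        stage = StageLabel(int(rng.choice(3, p=list(spec.stage_mixture))))
        person_id = f"p{k:04d}"
        records, stages = [], []
        for t in range(spec.occasions):
            occasion = _BASE_DATE + _dt.timedelta(days=30 * t)
            rec = _template_record(rng, stage, person_id, occasion, config)
            records.append(_perturb(rng, rec, spec.noise))
            stages.append(stage)
            u = rng.random()
            if u < spec.drift_down:
                stage = StageLabel(max(0, int(stage) - 1))
            elif u < spec.drift_down + spec.drift_up:
                stage = StageLabel(min(2, int(stage) + 1))
        out.append(HistoryFixture(person_id=person_id, records=records, latent_stages=stages))
    return out
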