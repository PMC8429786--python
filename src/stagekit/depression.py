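"""The depressive-syndrome secondary staging cascade.

Classifies one assessment's depressive presentation into three ordered
labels by walking an IF / ELSE-IF / ELSE cascade:

* **Stage 2+ — clear severe depressive syndrome** when a severe total
  (QIDS >= 21 OR PHQ-9 >= 20) coincides with two or more severe symptom
  flags (the A criterion: psychomotor, sleep, concentration, energy items
  at 3) and at least one other severe feature (the B criterion: probable
  hypomania / psychosis / comorbidity / substance misuse, severe
  suicidality, or an illness-course flag).
* **Stage 1b — moderate depression syndrome** when, failing that, a
  moderate-or-above total (QIDS >= 11 OR PHQ-9 >= 10) coincides with two
  or more moderate symptom flags (same items at 2) and one moderate B
  feature (possible-or-above screens; the course flag does not count at
  this level).
* **Stage 1a — non-specific, mild depressive syndrome** otherwise.

Every condition evaluated is recorded in the result's trace, so a reviewer
can see exactly which criteria fired and, for a 1a outcome, which branch
condition failed.

Where both instruments are present each condition is evaluated on each and
combined with OR, mirroring the printed "QIDS >= 21 OR PHQ-9 >= 20" form;
the most severe reading wins by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .config import RunConfig
from .models import (
    AssessmentRecord,
    ClinicalFlags,
    DepressionLabel,
    DepressionResult,
    OrdinalFlag,
    SeverityBand,
)
from .scales import SYMPTOM_DOMAINS, definition, score_scale, severity_band

Level = Literal["severe", "moderate"]


class DepressionNotEvaluable(ValueError):
    """No depression scale present: distinct from an all-false evaluation."""


@dataclass(frozen=True)
class SymptomFlagSet:
    """A-criterion item flags at one severity level."""

    psychomotor: bool
    sleep: bool
    concentration: bool
    energy: bool
    level: Level

    def count(self) -> int:
        return sum((self.psychomotor, self.sleep, self.concentration, self.energy))

    def fired(self) -> list[str]:
        return [d for d in SYMPTOM_DOMAINS if getattr(self, d)]


def symptom_flags(
    record: AssessmentRecord, level: Level, config: RunConfig
) -> SymptomFlagSet:
    """Evaluate the four A-criterion symptom flags, OR-ed across scales.

    Severe level: named item(s) at >= 3 (for sleep, the highest sleep item
    at 3, the item maximum). Moderate level: the same items at 2 — read as
    >= 2 by default, or as printed strict equality for the sleep criteria
    when ``literal_equality`` is set.
    """
    scales = list(record.scales)
    if not scales:
        raise DepressionNotEvaluable("record has no depression scale responses")
    thr = (
        config.depression.severe_item_threshold
        if level == "severe"
        else config.depression.moderate_item_threshold
    )
    flags = {d: False for d in SYMPTOM_DOMAINS}
    for resp in scales:
        d = definition(resp.scale_id)
        for domain in SYMPTOM_DOMAINS:
            items = d.symptom_items[domain]
            if domain == "sleep":
                value = max(resp.item(i) for i in items)
                if config.depression.literal_equality:
                    hit = value == thr
                else:
                    hit = value >= thr
            else:
                hit = any(resp.item(i) >= thr for i in items)
            flags[domain] = flags[domain] or hit
    return SymptomFlagSet(level=level, **flags)


# (feature name, flag attribute, level required at severe / moderate)
_B_FEATURES: tuple[tuple[str, str], ...] = (
    ("hypomanic_episodes", "hypomania"),
    ("psychotic_symptoms", "psychosis"),
    ("severe_suicidality", "severe_suicidality"),
    ("comorbidity", "comorbidity"),
    ("substance_misuse", "substance_misuse"),
)


def b_features(flags: ClinicalFlags, level: Level) -> list[str]:
    """B-criterion features fired at the given level.

    Severe requires *probable* screens and also counts the illness-course
    flag (early onset, previous severe episode, treatment resistance,
    recurrence); moderate requires only *possible* screens. Severe
    suicidality counts at both levels.
    """
    required = OrdinalFlag.PROBABLE if level == "severe" else OrdinalFlag.POSSIBLE
    prefix = "probable" if level == "severe" else "possible"
    fired: list[str] = []
    for name, attr in _B_FEATURES:
        value = getattr(flags, attr)
        if isinstance(value, bool):
            if value:
                fired.append(name)
        elif value >= required:
            fired.append(f"{prefix}_{name}")
    if level == "severe" and flags.course_flag:
        fired.append("illness_course_flag")
    return fired


def _band_reached(
    record: AssessmentRecord, config: RunConfig, band: SeverityBand
) -> tuple[bool, list[str]]:
    """Whether any scale total reaches the band; trace lines for each."""
    reached = False
    trace: list[str] = []
    for resp in record.scales:
        total = score_scale(resp, config)
        b = severity_band(resp.scale_id, total, config)
        trace.append(f"total:{resp.scale_id.value}={total} band={b.name.lower()}")
        if b >= band:
            reached = True
    return reached, trace


def stage_depression(record: AssessmentRecord, config: RunConfig | None = None) -> DepressionResult:
    """Run the depressive-syndrome cascade on one record.

    Raises :class:`DepressionNotEvaluable` when the record carries no
    depression scale; callers that must always triage catch this and let
    the depression criteria contribute nothing.
    """
    config = config or RunConfig()
    if not record.scales:
        raise DepressionNotEvaluable("record has no depression scale responses")

    trace: list[str] = []
    for resp in record.scales:
        if config.require_complete is False and resp.completeness < 1.0:
            trace.append(
                f"warning:incomplete:{resp.scale_id.value}"
                f"(completeness={resp.completeness:.2f})"
            )

    dep = config.depression

    # -- severe (stage 2+) branch -----------------------------------------
    severe_total, total_trace = _band_reached(record, config, SeverityBand.SEVERE)
    trace += total_trace
    sev_flags = symptom_flags(record, "severe", config)
    sev_b = b_features(record.flags, "severe")
    trace += [f"A_severe:{d}" for d in sev_flags.fired()]
    trace += [f"B_severe:{f}" for f in sev_b]
    sev_ok = (
        severe_total
        and sev_flags.count() >= dep.min_a_flags
        and len(sev_b) >= dep.min_b_features
    )
    trace.append(
        "severe_branch:"
        f"total={severe_total},a={sev_flags.count()}/{dep.min_a_flags},"
        f"b={len(sev_b)}/{dep.min_b_features}->{'fired' if sev_ok else 'failed'}"
    )
    if sev_ok:
        return DepressionResult(label=DepressionLabel.STAGE_2PLUS_SEVERE, trace=tuple(trace))

    # -- moderate (stage 1b) branch ---------------------------------------
    mod_total, _ = _band_reached(record, config, SeverityBand.MODERATE)
    mod_flags = symptom_flags(record, "moderate", config)
    mod_b = b_features(record.flags, "moderate")
    trace += [f"A_moderate:{d}" for d in mod_flags.fired()]
    trace += [f"B_moderate:{f}" for f in mod_b]
    mod_ok = (
        mod_total
        and mod_flags.count() >= dep.min_a_flags
        and len(mod_b) >= dep.min_b_features
    )
    trace.append(
        "moderate_branch:"
        f"total={mod_total},a={mod_flags.count()}/{dep.min_a_flags},"
        f"b={len(mod_b)}/{dep.min_b_features}->{'fired' if mod_ok else 'failed'}"
    )
    if mod_ok:
        return DepressionResult(label=DepressionLabel.STAGE_1B_MODERATE, trace=tuple(trace))

    return DepressionResult(label=DepressionLabel.STAGE_1A_MILD, trace=tuple(trace))
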