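"""Brute-force recovery of the engine's emergent decision thresholds.

A deployed configuration can be audited by scanning constructed inputs
through the *public* staging entry points and reading off where the
decision flips: e.g. the lowest QIDS-SR16 total that can yield the severe
depressive-syndrome label, holding two severe A-criterion items and one
severe B feature fixed. On the default configuration these sweeps recover
the published rule parameters (21/20 severe, 11/10 moderate, A-count 2,
B-count 1) as emergent properties of the cascade rather than echoing the
config values back.
"""

from __future__ import annotations

import datetime as _dt
from typing import Optional

from .config import RunConfig
from .depression import stage_depression
from .models import (
    AssessmentRecord,
    ClinicalFlags,
    DepressionLabel,
    OrdinalFlag,
    ScaleId,
    ScaleResponse,
)
from .scales import definition

_OCCASION = _dt.date(2024, 1, 8)

# A-criterion anchor items per scale: (psychomotor, energy) for the severe
# sweeps, (concentration, energy) for the moderate sweeps.
_SEVERE_ANCHORS = {ScaleId.QIDS_SR16: (15, 14), ScaleId.PHQ9: (8, 4)}
_MODERATE_ANCHORS = {ScaleId.QIDS_SR16: (10, 14), ScaleId.PHQ9: (7, 4)}


def fill_items(
    scale_id: ScaleId, total: int, fixed: dict[int, int], cap: int = 3
) -> Optional[dict[int, int]]:
    """Deterministically construct an item vector with the given total.

    Items in ``fixed`` are pinned; remaining domains are filled greedily up
    to ``cap`` per domain until the scale total (domain-max scoring for
    QIDS) reaches ``total``. Returns None when the total is unreachable.
    """
    d = definition(scale_id)
    items = dict(fixed)
    fixed_domains = [dom for dom in d.domains if any(i in fixed for i in dom)]
    free_domains = [dom for dom in d.domains if not any(i in fixed for i in dom)]
    base = sum(max(items.get(i, 0) for i in dom) for dom in fixed_domains)
    remaining = total - base
    if not 0 <= remaining <= cap * len(free_domains):
        return None
    for dom in free_domains:
        v = min(cap, remaining)
        items[dom[0]] = v
        remaining -= v
    return items


def _single_scale_record(
    scale_id: ScaleId, items: dict[int, int], flags: ClinicalFlags
) -> AssessmentRecord:
    return AssessmentRecord(
        person_id="sweep",
        occasion=_OCCASION,
        scales=(ScaleResponse(scale_id=scale_id, items=items),),
        flags=flags,
    )


def min_total_for_severe_label(
    scale_id: ScaleId, config: RunConfig | None = None
) -> Optional[int]:
    """Lowest total on one scale that can yield the severe (2+) depressive
    label, with two severe A items and one severe B feature held present.

    Scans totals 0-27; the other scale is absent.
    """
    config = config or RunConfig()
    thr = config.depression.severe_item_threshold
    a1, a2 = _SEVERE_ANCHORS[scale_id]
    flags = ClinicalFlags(psychosis=OrdinalFlag.PROBABLE)
    for total in range(0, 28):
        items = fill_items(scale_id, total, {a1: thr, a2: thr})
        if items is None:
            continue
        res = stage_depression(_single_scale_record(scale_id, items, flags), config)
        if res.label is DepressionLabel.STAGE_2PLUS_SEVERE:
            return total
    return None


def min_total_for_moderate_label(
    scale_id: ScaleId, config: RunConfig | None = None
) -> Optional[int]:
    """Lowest total that can yield the moderate (1b) depressive label.

    Two moderate A items (concentration, energy) and one moderate B
    feature (possible substance misuse) are held present; fill items are
    capped below the severe item threshold so the severe branch cannot
    fire through the filler.
    """
    config = config or RunConfig()
    mod = config.depression.moderate_item_threshold
    cap = max(config.depression.severe_item_threshold - 1, mod)
    a1, a2 = _MODERATE_ANCHORS[scale_id]
    flags = ClinicalFlags(substance_misuse=OrdinalFlag.POSSIBLE)
    for total in range(0, 28):
        items = fill_items(scale_id, total, {a1: mod, a2: mod}, cap=cap)
        if items is None:
            continue
        res = stage_depression(_single_scale_record(scale_id, items, flags), config)
        if res.label is DepressionLabel.STAGE_1B_MODERATE:
            return total
    return None


def _qids_items_with_k_severe_flags(k: int, config: RunConfig) -> dict[int, int]:
    """QIDS items with exactly ``k`` severe A flags and a severe-band total.

    The first ``k`` A-criterion anchors (psychomotor 15, energy 14,
    concentration 10, sleep 1) sit at the severe item threshold; the
    remaining A-capable domains sit just below it; the five non-A domains
    (sad mood, appetite/weight, self-view, suicidal ideation, interest)
    carry the rest of the total, which they can because they do not feed
    any symptom flag.
    """
    thr = config.depression.severe_item_threshold
    anchors = [15, 14, 10, 1]
    items = {i: thr for i in anchors[:k]}
    for i in anchors[k:]:
        items[i] = thr - 1
    for i in (5, 6, 11, 12, 13):  # one representative item per non-A domain
        items[i] = 3
    return items


def min_a_flag_count_for_severe(config: RunConfig | None = None) -> Optional[int]:
    """Smallest number of fired severe A symptom flags that permits the
    severe label, with a severe-band total and one severe B feature
    present throughout the scan."""
    config = config or RunConfig()
    flags = ClinicalFlags(psychosis=OrdinalFlag.PROBABLE)
    for count in range(0, 5):
        items = _qids_items_with_k_severe_flags(count, config)
        res = stage_depression(
            _single_scale_record(ScaleId.QIDS_SR16, items, flags), config
        )
        if res.label is DepressionLabel.STAGE_2PLUS_SEVERE:
            return count
    return None


def min_b_feature_count_for_severe(config: RunConfig | None = None) -> Optional[int]:
    """Smallest number of severe B features that permits the severe label,
    with a severe-band total and two severe A flags present."""
    config = config or RunConfig()
    items = _qids_items_with_k_severe_flags(2, config)
    b_sets = [
        ClinicalFlags(),
        ClinicalFlags(psychosis=OrdinalFlag.PROBABLE),
        ClinicalFlags(psychosis=OrdinalFlag.PROBABLE, hypomania=OrdinalFlag.PROBABLE),
    ]
    for count, flags in enumerate(b_sets):
        res = stage_depression(
            _single_scale_record(ScaleId.QIDS_SR16, items, flags), config
        )
        if res.label is DepressionLabel.STAGE_2PLUS_SEVERE:
            return count
    return None
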