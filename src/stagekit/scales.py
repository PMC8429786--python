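"""Scale registry and scoring for the supported depression instruments.

Two self-report instruments are registered out of the box:

* **QIDS-SR16** — 16 items scored as 9 symptom domains. Three domains take
  the *maximum* of their constituent items (sleep = items 1-4,
  appetite/weight = items 6-9, psychomotor = items 15-16); the other six
  domains are single items. Total range 0-27.
* **PHQ-9** — 9 items, simple sum, total range 0-27.

The registry also fixes the item mapping used by the symptom-flag criteria
of the depressive staging cascade (psychomotor, sleep, concentration,
energy), so the same clinical concept is read off whichever instrument a
service administers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .models import ScaleId, ScaleResponse, SeverityBand


class WrongScaleError(ValueError):
    """Raised when a response is scored against the wrong instrument."""


class UnknownScaleError(KeyError):
    pass


class IncompleteScaleError(ValueError):
    """Raised under ``require_complete`` when items are unanswered."""


# Symptom domains used by the A criterion of the depressive cascade.
SYMPTOM_DOMAINS = ("psychomotor", "sleep", "concentration", "energy")


@dataclass(frozen=True)
class ScaleDefinition:
    """Structural description of one instrument.

    ``domains`` drives total scoring: each inner tuple is one domain whose
    score is the max over its items. ``symptom_items`` maps each A-criterion
    symptom domain to the item numbers that express it on this instrument.
    """

    scale_id: ScaleId
    n_items: int
    domains: tuple[tuple[int, ...], ...]
    symptom_items: dict[str, tuple[int, ...]]
    # Sleep is banded by the *highest* sleep item, so the printed severe
    # criterion "highest score on sleep items = 3" is an equality at the
    # item maximum; flag evaluation takes the max over these items.
    max_total: int = 27


REGISTRY: dict[ScaleId, ScaleDefinition] = {
    ScaleId.QIDS_SR16: ScaleDefinition(
        scale_id=ScaleId.QIDS_SR16,
        n_items=16,
        domains=(
            (1, 2, 3, 4),    # sleep: onset, mid-nocturnal, early waking, hypersomnia
            (5,),            # sad mood
            (6, 7, 8, 9),    # appetite/weight change
            (10,),           # concentration / decision making
            (11,),           # self-view
            (12,),           # thoughts of death or suicide
            (13,),           # general interest
            (14,),           # energy level
            (15, 16),        # psychomotor slowing / agitation
        ),
        symptom_items={
            "psychomotor": (15, 16),
            "sleep": (1, 2, 3, 4),
            "concentration": (10,),
            "energy": (14,),
        },
    ),
    ScaleId.PHQ9: ScaleDefinition(
        scale_id=ScaleId.PHQ9,
        n_items=9,
        domains=tuple((i,) for i in range(1, 10)),
        symptom_items={
            "psychomotor": (8,),
            "sleep": (3,),
            "concentration": (7,),
            "energy": (4,),
        },
    ),
}


def definition(scale_id: ScaleId) -> ScaleDefinition:
    try:
        return REGISTRY[scale_id]
    except KeyError:
        raise UnknownScaleError(f"unknown scale {scale_id!r}") from None


def _score(resp: ScaleResponse, expected: ScaleId, config: RunConfig | None) -> int:
    if resp.scale_id is not expected:
        raise WrongScaleError(
            f"expected a {expected.value} response, got {resp.scale_id.value}"
        )
    if config is not None and config.require_complete and resp.completeness < 1.0:
        raise IncompleteScaleError(
            f"{resp.scale_id.value} has {resp.n_items - len(resp.items)} unanswered item(s)"
        )
    d = definition(resp.scale_id)
    # unanswered items score 0 (callers surface a completeness warning)
    return sum(max(resp.item(i) for i in domain) for domain in d.domains)


def score_qids(resp: ScaleResponse, config: RunConfig | None = None) -> int:
    """QIDS-SR16 total: sum of the 9 domain scores, range 0-27."""
    return _score(resp, ScaleId.QIDS_SR16, config)


def score_phq9(resp: ScaleResponse, config: RunConfig | None = None) -> int:
    """PHQ-9 total: simple sum of the 9 items, range 0-27."""
    return _score(resp, ScaleId.PHQ9, config)


def score_scale(resp: ScaleResponse, config: RunConfig | None = None) -> int:
    """Score any registered instrument."""
    if resp.scale_id is ScaleId.QIDS_SR16:
        return score_qids(resp, config)
    if resp.scale_id is ScaleId.PHQ9:
        return score_phq9(resp, config)
    raise UnknownScaleError(f"unknown scale {resp.scale_id!r}")


def severity_band(scale_id: ScaleId, total: int, config: RunConfig) -> SeverityBand:
    """Band a total score: severe / moderate / none-mild.

    Defaults: QIDS severe >= 21, moderate >= 11; PHQ-9 severe >= 20,
    moderate >= 10.
    """
    d = definition(scale_id)
    if not 0 <= total <= d.max_total:
        raise ValueError(f"total {total} outside 0-{d.max_total} for {scale_id.value}")
    cut = config.cutoffs(scale_id)
    if total >= cut.severe:
        return SeverityBand.SEVERE
    if total >= cut.moderate:
        return SeverityBand.MODERATE
    return SeverityBand.NONE_MILD
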