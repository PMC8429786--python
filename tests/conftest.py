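import datetime as dt

import pytest
from hypothesis import settings

from stagekit import (
    AssessmentRecord,
    ClinicalFlags,
    Functioning,
    FunctioningBand,
    RunConfig,
    ScaleId,
    ScaleResponse,
)

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")

OCCASION = dt.date(2024, 1, 8)


def qids(items) -> ScaleResponse:
    """Build a QIDS-SR16 response from a 16-list or {item: value} dict."""
    if isinstance(items, dict):
        d = items
    else:
        d = {i + 1: v for i, v in enumerate(items)}
    return ScaleResponse(scale_id=ScaleId.QIDS_SR16, items=d)


def phq9(items) -> ScaleResponse:
    if isinstance(items, dict):
        d = items
    else:
        d = {i + 1: v for i, v in enumerate(items)}
    return ScaleResponse(scale_id=ScaleId.PHQ9, items=d)


def make_record(
    qids_items=None,
    phq9_items=None,
    flags=None,
    functioning=None,
    person_id="p1",
    occasion=OCCASION,
) -> AssessmentRecord:
    scales = []
    if qids_items is not None:
        scales.append(qids(qids_items))
    if phq9_items is not None:
        scales.append(phq9(phq9_items))
    if functioning is None:
        functioning = Functioning(band=FunctioningBand.NONE_MILD)
    elif isinstance(functioning, FunctioningBand):
        functioning = Functioning(band=functioning)
    return AssessmentRecord(
        person_id=person_id,
        occasion=occasion,
        scales=tuple(scales),
        flags=flags or ClinicalFlags(),
        functioning=functioning,
    )


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()
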