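"""Score one young person's intake assessment and stage it.

Builds a single assessment record — QIDS-SR16 item answers, clinical
flags, a functioning rating — scores the scale, runs the depressive
secondary cascade and the transdiagnostic primary cascade, and prints the
assigned stage with the full criterion trace.
"""

import datetime as dt

from stagekit import (
    AssessmentRecord,
    ClinicalFlags,
    Functioning,
    FunctioningBand,
    OrdinalFlag,
    ScaleId,
    ScaleResponse,
    schedule_review,
    score_qids,
    stage_record,
)
from stagekit.report import render_result

# A severe presentation: QIDS total 23 (note the domain-max scoring: the
# four sleep items 1-4 count once, via their maximum), psychomotor and
# energy items at 3, probable psychotic symptoms, major functioning impact.
record = AssessmentRecord(
    person_id="demo-001",
    occasion=dt.date(2024, 3, 4),
    scales=(
        ScaleResponse(
            scale_id=ScaleId.QIDS_SR16,
            items={1: 2, 2: 1, 3: 0, 4: 1, 5: 3, 6: 0, 7: 0, 8: 1, 9: 0,
                   10: 3, 11: 3, 12: 2, 13: 3, 14: 3, 15: 3, 16: 0},
        ),
    ),
    flags=ClinicalFlags(psychosis=OrdinalFlag.PROBABLE),
    functioning=Functioning(band=FunctioningBand.MAJOR_ONGOING),
)

total = score_qids(record.scales[0])
print(f"QIDS-SR16 total (9-domain scoring): {total}")

result = stage_record(record)
print(render_result(result))
print(f"next review due in {schedule_review(result.stage)} days")

# The stage is 2+ because three things coincide: a severe-band total
# (>= 21), two or more severe symptom flags (psychomotor, concentration,
# energy at 3), and a severe B feature (probable psychotic symptoms) —
# plus major functioning impact at the primary cascade.
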