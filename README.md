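# stagekit

Rule-based transdiagnostic **clinical staging** for youth mental health
triage: a tested, configurable decision-support engine that turns a young
person's intake self-report data into a suggested clinical stage.

Most mental disorders emerge before age 25, and services struggle to match
heterogeneous presentations to the right intensity of care. Clinical
staging places a person on an illness continuum — from non-specific mild
symptoms to full-threshold, persistent disorder — by severity, persistence
and functional impact, analogously to staging in oncology. `stagekit`
implements the automated form of that triage decision for the three stages
that matter most for early intervention:

| stage | meaning |
|-------|---------|
| 1a | non-specific symptoms, mild-to-moderate severity, recent/mild functional impact |
| 1b | attenuated syndrome: more specific, moderate-to-severe symptoms and functional impact |
| 2+ | full-threshold, discrete, persistent or recurrent disorder (stages 2-4 collapsed for triage) |

The engine is aimed at researchers and service developers who need a
standardized, auditable staging rule they can run over assessment exports,
stress-test under synthetic cohorts, and compare against clinician
judgement. It is a decision *support* tool: every output carries the full
criterion trace, and disagreement with a clinician is escalated, never
overridden.

## The staging rules

**Primary cascade** (transdiagnostic). With `F` the social/occupational
functioning band and pre-resolved syndrome indicators:

```
IF   F = major_ongoing AND (manic ∨ psychotic ∨ severe-depressive ∨
                            severe-anxiety ∨ hospitalization ∨ probable comorbidity)
THEN stage 2+
ELIF F ≥ moderate_severe AND (specific severe anxiety ∨ moderate depression ∨
                              hypomanic/attenuated-psychotic symptoms ∨
                              possible comorbidity/substance misuse)
THEN stage 1b
ELSE stage 1a
```

**Depressive secondary cascade.** The "severe depressive syndrome" and
"moderate depression" indicators come from scale data:

```
severe:    (QIDS ≥ 21 ∨ PHQ-9 ≥ 20)  ∧  |A₃| ≥ 2  ∧  |B_probable| ≥ 1
moderate:  (QIDS ≥ 11 ∨ PHQ-9 ≥ 10)  ∧  |A₂| ≥ 2  ∧  |B_possible| ≥ 1
```

where `A_t` is the set of symptom flags — psychomotor, sleep,
concentration, energy items at threshold `t` on either instrument — and
`B` is the set of other specific features (hypomanic episodes, psychotic
symptoms, severe suicidality, comorbidity, substance misuse; plus an
illness-course flag at the severe level). QIDS-SR16 totals use the
published 9-domain scoring (sleep, appetite/weight and psychomotor domains
take the maximum of their items); PHQ-9 is a simple sum. Both cutoffs and
item thresholds live in a YAML config with these values as defaults.

**Longitudinal rules.** Assigned stages only ratchet upward over a
person's history (remission never lowers a stage), and review intervals
shorten with stage severity (defaults 90 / 30 / 14 days for 1a / 1b / 2+).

## Worked example

```python
import datetime as dt
from stagekit import (AssessmentRecord, ClinicalFlags, Functioning,
                      FunctioningBand, OrdinalFlag, ScaleId, ScaleResponse,
                      stage_record)

record = AssessmentRecord(
    person_id="demo-001", occasion=dt.date(2024, 3, 4),
    scales=(ScaleResponse(scale_id=ScaleId.QIDS_SR16,
            items={1: 2, 2: 1, 3: 0, 4: 1, 5: 3, 6: 0, 7: 0, 8: 1, 9: 0,
                   10: 3, 11: 3, 12: 2, 13: 3, 14: 3, 15: 3, 16: 0}),),
    flags=ClinicalFlags(psychosis=OrdinalFlag.PROBABLE),
    functioning=Functioning(band=FunctioningBand.MAJOR_ONGOING),
)
result = stage_record(record)
print(result.stage.code, result.fired_criteria[:3])
```

Running `python examples/01_score_and_stage.py` (this record) prints:

```
QIDS-SR16 total (9-domain scoring): 23
### demo-001 @ 2024-03-04 -> stage 2+
fired criteria:
  - functioning=major_ongoing
  - functioning:major_ongoing_impact
  - 2+:clear_severe_depressive_syndrome
  - depression|total:QIDS_SR16=23 band=severe
  - depression|A_severe:psychomotor
  - depression|A_severe:concentration
  - depression|A_severe:energy
  - depression|B_severe:probable_psychotic_symptoms
  - depression|severe_branch:total=True,a=3/2,b=1/1->fired
next review due in 14 days
```

The stage is 2+ because a severe-band total (23 ≥ 21), three severe
symptom flags (two required) and a severe B feature (probable psychotic
symptoms) coincide with major functioning impact; a 2+ case is re-reviewed
after 14 days. The other scripts under `examples/` demonstrate synthetic
cohorts and noise-recovery curves, the stage ratchet, the clinician
concordance audit, and brute-force threshold recovery.

## Command line

A thin CLI wraps the library:

```bash
stagekit simulate --n 300 --seed 42 --noise 0.1 --out cohort.csv   # + latent-truth sidecar
stagekit run --input cohort.csv --out results.json                 # stage every record
stagekit review --results results.json --reviews clinician.csv --out entries.csv
stagekit report --results results.json --reviews entries.csv       # stage mix + concordance
```

Input schemas (CSV columns, JSON layout) are documented in
`stagekit/io.py` and `stagekit/data/assessment_record.schema.json`; all
thresholds can be overridden with `--config my.yaml` (see
`stagekit/data/default_config.yaml`).

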