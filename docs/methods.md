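# Methods

## Model

`stagekit` implements a deterministic, rule-based triage model: a pair of
nested IF / ELSE-IF / ELSE cascades that map one person-occasion
assessment to an ordered clinical stage (1a < 1b < 2+). The model's core
assumption is the clinical-staging one — that severity, specificity and
functional impact jointly locate a young person on an illness continuum,
and that this placement is *irreversible* (the ratchet). The engine does
not model uncertainty: boolean/ordinal criteria either fire or they do
not, and the output is a stage plus the complete list of fired criteria,
so a clinician can audit exactly why a stage was suggested. It is
explicitly a decision-support heuristic, not a diagnostic instrument.

### Primary (transdiagnostic) cascade

Stage 2+ requires *major and ongoing* functional impact plus at least one
full-threshold syndrome indicator (clear manic, psychotic, severe
depressive or severe anxiety syndrome; previous psychiatric
hospitalization; probable comorbidity). Stage 1b requires at least
*moderate-to-severe* impact plus at least one attenuated-syndrome
indicator (specific severe anxiety, a moderate depressive syndrome,
possible hypomanic/attenuated-psychotic symptoms, possible
comorbidity/substance misuse). Everything else is 1a. The 2+ branch is
always evaluated first, so a presentation satisfying both branches stages
2+.

Functioning bands are ordered, and "major" satisfies the 1b branch's
"moderate-to-severe" requirement. A person with major impairment but no
listed syndrome falls through to 1a — the literal reading of the cascade;
the engine assigns 1a and attaches a warning recommending clinical
review, because refusing to triage would be worse than triaging
conservatively with a caveat.

### Depressive secondary cascade

The only published secondary algorithm is the depressive one; other
syndromes enter the primary cascade as pre-resolved flags. The severe
branch fires when all three hold: a severe-band total (QIDS-SR16 ≥ 21 or
PHQ-9 ≥ 20), at least two of four severe symptom flags (psychomotor,
sleep, concentration, energy items at 3 on either instrument), and at
least one severe B feature (probable hypomanic episodes / psychotic
symptoms / comorbidity / substance misuse, severe suicidality, or an
illness-course flag covering early onset, previous severe episode,
treatment resistance or recurrence). The moderate branch is the analogue
at ≥ 11 / ≥ 10 totals and item threshold 2, with possible-level B
features and no course flag. When both instruments are present every
condition is evaluated on each and combined with OR; the most severe
reading wins by construction.

A record with no depression scale raises a distinct "not evaluable"
signal; the primary cascade catches it, lets the depressive criteria
contribute nothing, and adds a warning — triage always yields a stage.

## Parameters

All thresholds are configuration, not code, with defaults in
`stagekit/data/default_config.yaml`:

| parameter | default | unit | rationale |
|---|---|---|---|
| QIDS severe / moderate cutoff | 21 / 11 | total score | published severity banding of QIDS-SR16 |
| PHQ-9 severe / moderate cutoff | 20 / 10 | total score | published severity banding of PHQ-9 |
| severe / moderate item threshold | 3 / 2 | item response | "severe" vs "moderate" endorsement on a 0-3 Likert item |
| A-flag minimum | 2 | count | "two or more symptoms" |
| B-feature minimum | 1 | count | "at least one other specific feature" |
| functioning edges | ≤ 50 major, 51-70 moderate-severe | 0-100 score | no instrument is mandated; edges are a stated default for services using a 0-100 rating (e.g. SOFAS-like), not doctrine |
| review intervals | 90 / 30 / 14 | days | 1b = 1 month is the stated default; 1a and 2+ are chosen to satisfy the constraint that later stages get more frequent follow-up, and validated (strictly decreasing) at config load |

Invalid orderings — a moderate cutoff above a severe one, non-decreasing
review intervals, inverted functioning edges — are rejected when the
configuration is loaded, not at staging time.

## Numerical and interpretive choices

**QIDS-SR16 scoring.** The 16 items collapse to 9 symptom domains; sleep
(items 1-4), appetite/weight (6-9) and psychomotor (15-16) score as the
maximum of their items. This is the instrument's published scoring rule,
which the item-level criteria ("highest score on sleep items")
presuppose.

**Missing items** score 0 by default; the record's completeness is
surfaced as a warning in the trace. This is deliberately conservative —
missingness can only under-call severity, never fabricate it. Services
preferring hard validation set `require_complete: true`, which rejects
incomplete scales instead.

**"= 2" vs "≥ 2".** The printed moderate sleep criteria use strict
equality ("sleep item = 2") while the neighbouring criteria use "≥ 2".
Literal equality makes the cascade non-monotone: worsening sleep from 2
to 3 would switch the moderate flag off. The default reads every moderate
item criterion as ≥ 2 (severity bands nest: a severe symptom implies at
least a moderate one); `depression.literal_equality: true` restores the
printed equality exactly.

**Severe depression below major functioning.** Read literally, the 1b
branch's depressive criterion is "moderate depression syndrome" — so a
person whose depressive syndrome is *severe* but whose functioning is
only moderate-to-severe would satisfy neither branch and be staged 1a.
That makes the composed pipeline non-monotone (worsening one item could
drop the stage from 1b to 1a) and is clinically indefensible, so by
default a severe depressive syndrome also satisfies the 1b depressive
criterion (`staging.count_severe_depression_for_1b: true`); the strict
printed reading remains available as a config switch. This was the one
place the engine deviates from the literal rule text by default, and the
monotonicity suite (10,000 single-increment record pairs) is what forces
the choice.

**B-feature semantics.** No instruments or cutoffs are mandated for the
hypomania / psychosis / comorbidity / substance screens, so they enter as
pre-resolved none/possible/probable ordinals in the input schema rather
than being derived from invented psychometric cutoffs. "Severe
suicidality" is likewise a boolean input. The 2+ branch's "significant
and ongoing" comorbidity maps to probable, the 1b branch's "significant"
to possible; both mappings are config.

**Ties and degenerate inputs.** Duplicate same-day occasions keep
insertion order; histories with out-of-order dates are rejected. An
assessment with neither scales, flags nor functioning is invalid. Staging
is total on valid input: every record gets a stage.

## Synthetic cohorts

The generator emulates service-intake records with a controllable latent
stage. Templates are built constructively from the *configured*
thresholds (not hard-coded numbers): a 2+ template combines a
severe-band total, psychomotor and energy anchors at the severe item
threshold, one severe B feature and major functioning; a 1b template the
moderate analogues with fill items capped below the severe item
threshold; a 1a template sub-threshold items, no flags, mild functioning.
The noise model is the simplest exchangeable perturbation: each item is
independently resampled uniformly on 0-3 with probability `noise`, each
flag and the functioning band independently resampled with the same
probability.

Default conditions used throughout the tests: mixture (0.5, 0.3, 0.2)
over (1a, 1b, 2+), n = 300 for recovery checks, noise grid
0 / 0.1 / 0.25 / 0.5, single occasion; longitudinal fixtures use 4
occasions with per-step remission probability 0.25 and progression
probability 0.15, which reliably produces remitting trajectories so
ratchet tests bite.

What passing these tests shows — and does not show. Noise-free recovery
and the decay curve validate the *engine's* internal consistency: records
built to a stage's criteria are staged accordingly, and grading degrades
gracefully under perturbation. They say nothing about real populations:
the generator has no item correlations, no informative missingness, no
prevalence realism, and its flags are exactly as reliable as the
perturbation makes them. Clinical validity of the staging rule itself is
an open empirical question outside this package's scope.

## Verification design

The cascades are verified against independently written truth-table
oracles over exhaustive criterion grids (972 record combinations for the
depressive cascade, 31,104 bundle combinations for the primary cascade),
and the printed rule parameters (21 / 20 / 11 / 10 cutoffs, A-count 2,
B-count 1) are recovered by brute-force sweeps through the public API
rather than read from config — the sweep in `stagekit.sweeps` is also the
deployment-audit tool. Problem sizes (10,000 monotonicity pairs, 300-person
cohorts, 50 random trajectories, exhaustive 5-element permutations) keep
the full suite under a few seconds while leaving each property's failure
modes plenty of room to surface.

## Known limitations

* Only the depressive secondary cascade is implemented; anxiety, mania
  and psychosis enter as pre-resolved flags (no published secondary
  algorithms exist for them).
* No cross-instrument score linking: QIDS and PHQ-9 bands are treated as
  exchangeable evidence via OR, though the instruments are not
  psychometrically equivalent; IRT-based linking is explicitly out of
  scope.
* Stages 2, 3 and 4 are not differentiated; the output vocabulary is
  {1a, 1b, 2+}.
* The functioning instrument is unspecified by design; the 0-100 band
  edges are service configuration.
* No treatment recommendation: the engine suggests a stage and schedules
  reviews, nothing more.
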