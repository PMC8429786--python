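# stagekit default configuration: every numeric threshold the engine uses.
# Edit a copy of this file and pass it via --config / load_config().
scale_cutoffs:
  QIDS_SR16:
    moderate: 11
    severe: 21
  PHQ9:
    moderate: 10
    severe: 20
depression:
  severe_item_threshold: 3
  moderate_item_threshold: 2
  min_a_flags: 2
  min_b_features: 1
  literal_equality: false
functioning:
  major_max: 50.0
  moderate_max: 70.0
staging:
  comorbidity_2plus: 2
  comorbidity_1b: 1
  substance_1b: 1
  hypomania_1b: 1
  psychosis_1b: 1
  count_severe_depression_for_1b: true
review_intervals:
  stage_1a: 90
  stage_1b: 30
  stage_2_plus: 14
require_complete: false
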