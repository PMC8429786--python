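"""Recover the engine's decision thresholds by brute force.

Sweeps constructed records through the public staging entry points and
reads off where each decision flips. On the default configuration this
recovers the published rule parameters as emergent properties of the
cascade — useful as a deployment audit when cutoffs are customized.
"""

from stagekit import (
    ScaleId,
    min_a_flag_count_for_severe,
    min_b_feature_count_for_severe,
    min_total_for_moderate_label,
    min_total_for_severe_label,
)

print("minimum QIDS total for the severe (2+) depressive label :",
      min_total_for_severe_label(ScaleId.QIDS_SR16))
print("minimum PHQ-9 total for the severe (2+) depressive label:",
      min_total_for_severe_label(ScaleId.PHQ9))
print("minimum QIDS total for the moderate (1b) label          :",
      min_total_for_moderate_label(ScaleId.QIDS_SR16))
print("minimum PHQ-9 total for the moderate (1b) label         :",
      min_total_for_moderate_label(ScaleId.PHQ9))
print("minimum severe symptom-flag (A) count                   :",
      min_a_flag_count_for_severe())
print("minimum severe B-feature count                          :",
      min_b_feature_count_for_severe())
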