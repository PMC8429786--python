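"""Longitudinal staging: the stage ratchet and review scheduling.

Generates multi-occasion trajectories whose latent stage drifts — including
remissions — and shows that the ratcheted stage never decreases even when
the per-occasion presentation improves.
"""

from stagekit import (
    CohortSpec,
    StageHistory,
    apply_stage_ratchet,
    generate_history,
    ratchet_trajectory,
    schedule_review,
    stage_record,
)

fixtures = generate_history(CohortSpec(n=50, seed=21, occasions=4))

# pick someone whose raw stage drops at some point (a remission)
remitting = next(
    f for f in fixtures
    if any(b < a for a, b in zip(f.latent_stages, f.latent_stages[1:]))
)

results = [stage_record(r) for r in remitting.records]
history = StageHistory(person_id=remitting.person_id, results=results)
ratcheted = ratchet_trajectory(history)

print(f"person {remitting.person_id}:")
print("  per-occasion stage :", " -> ".join(r.stage.code for r in results))
print("  ratcheted stage    :", " -> ".join(s.code for s in ratcheted))
current = apply_stage_ratchet(history)
print(f"  current stage {current.code}; next review in {schedule_review(current)} days")

# The ratcheted line never steps down: once on the staging continuum a
# young person keeps their highest stage, and review frequency follows it
# (1a: 90 d, 1b: 30 d, 2+: 14 d by default).
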