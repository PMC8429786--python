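"""Human-readable staging and concordance reports (plain text / markdown).

Every number rendered here is taken from the serialized results or the
concordance summary — the renderer does no arithmetic of its own beyond
counting, so reports are always recomputable from the artifacts they
describe.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

from .models import StageLabel, StagingResult
from .staging import ConcordanceReport


def render_result(result: StagingResult) -> str:
    lines = [
        f"### {result.person_id} @ {result.occasion.isoformat()} -> stage {result.stage.code}",
        "fired criteria:",
    ]
    lines += [f"  - {c}" for c in result.fired_criteria]
    if result.warnings:
        lines.append("warnings:")
        lines += [f"  ! {w}" for w in result.warnings]
    return "\n".join(lines)


def render_cohort_summary(results: Sequence[StagingResult]) -> str:
    counts = Counter(r.stage for r in results)
    lines = [f"## Staging summary ({len(results)} assessments)"]
    for stage in StageLabel:
        lines.append(f"  stage {stage.code:<3} {counts.get(stage, 0)}")
    return "\n".join(lines)


def render_concordance(report: ConcordanceReport) -> str:
    lines = [
        "## Clinician concordance",
        f"  review entries : {report.n_entries}",
        f"  agreement rate : {report.agreement_rate:.4g}",
        f"  MDT referrals  : {report.referral_count}",
        "",
        "  confusion (rows = protocol, cols = clinician):",
    ]
    lines += ["  " + line for line in report.confusion.to_string().splitlines()]
    return "\n".join(lines)


def render_report(
    results: Sequence[StagingResult],
    concordance: Optional[ConcordanceReport] = None,
    per_person: bool = True,
) -> str:
    """Full report: cohort stage distribution, per-person traces,
    optional concordance block."""
    blocks = [render_cohort_summary(results)]
    if per_person:
        blocks += [render_result(r) for r in results]
    if concordance is not None:
        blocks.append(render_concordance(concordance))
    return "\n\n".join(blocks) + "\n"
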