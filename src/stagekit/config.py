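"""Run configuration: every numeric threshold the staging engine uses.

All thresholds live here with the published rule parameters as defaults,
so a service deploying different cutoffs (or a different functioning
instrument) only edits a YAML file. Invalid orderings — a moderate cutoff
above the severe one, review intervals that do not shorten as stage
severity rises — are rejected at load time.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .models import FunctioningBand, OrdinalFlag, ScaleId, StageLabel


class ScaleCutoffs(BaseModel):
    """Severity-band cutoffs on a scale's total score."""

    model_config = ConfigDict(frozen=True)

    moderate: int = Field(ge=0, le=27)
    severe: int = Field(ge=0, le=27)

    @model_validator(mode="after")
    def _ordered(self) -> "ScaleCutoffs":
        if self.moderate > self.severe:
            raise ValueError(
                f"moderate cutoff {self.moderate} exceeds severe cutoff {self.severe}"
            )
        return self


class DepressionConfig(BaseModel):
    """Parameters of the depressive-syndrome secondary algorithm."""

    model_config = ConfigDict(frozen=True)

    severe_item_threshold: int = 3
    moderate_item_threshold: int = 2
    min_a_flags: int = 2       # "two or more symptoms"
    min_b_features: int = 1    # "at least one other specific feature"
    # If true, the moderate sleep criteria use strict equality ("= 2") as
    # printed; the default reads every moderate item criterion as >= 2,
    # which keeps the cascade monotone (a severe symptom implies at least
    # a moderate one).
    literal_equality: bool = False


class FunctioningEdges(BaseModel):
    """Band edges for mapping a 0-100 functioning score (lower = worse)."""

    model_config = ConfigDict(frozen=True)

    major_max: float = 50.0     # score <= major_max        -> major_ongoing
    moderate_max: float = 70.0  # major_max < score <= this -> moderate_severe

    @model_validator(mode="after")
    def _ordered(self) -> "FunctioningEdges":
        if not self.major_max < self.moderate_max:
            raise ValueError("functioning edges must satisfy major_max < moderate_max")
        return self

    def band_for_score(self, score: float) -> FunctioningBand:
        if score <= self.major_max:
            return FunctioningBand.MAJOR_ONGOING
        if score <= self.moderate_max:
            return FunctioningBand.MODERATE_SEVERE
        return FunctioningBand.NONE_MILD


class StagingBranchConfig(BaseModel):
    """Ordinal levels required by the transdiagnostic cascade's branches."""

    model_config = ConfigDict(frozen=True)

    # "Significant and ongoing comorbid syndromes" (2+) vs "Significant
    # comorbid syndromes" (1b)
    comorbidity_2plus: OrdinalFlag = OrdinalFlag.PROBABLE
    comorbidity_1b: OrdinalFlag = OrdinalFlag.POSSIBLE
    substance_1b: OrdinalFlag = OrdinalFlag.POSSIBLE
    hypomania_1b: OrdinalFlag = OrdinalFlag.POSSIBLE
    psychosis_1b: OrdinalFlag = OrdinalFlag.POSSIBLE
    # The 1b branch's depressive criterion reads "moderate depression
    # syndrome". By default a *severe* depressive syndrome also satisfies
    # it, so someone with a clear severe syndrome but sub-major functioning
    # is staged 1b rather than falling through to 1a (keeps the composed
    # cascade monotone). Set false for the strict printed reading.
    count_severe_depression_for_1b: bool = True


class ReviewIntervals(BaseModel):
    """Days until the next scheduled stage review, by current stage."""

    model_config = ConfigDict(frozen=True)

    stage_1a: int = Field(default=90, gt=0)
    stage_1b: int = Field(default=30, gt=0)   # "stage 1b after 1 month"
    stage_2_plus: int = Field(default=14, gt=0)

    @model_validator(mode="after")
    def _strictly_decreasing(self) -> "ReviewIntervals":
        if not self.stage_1a > self.stage_1b > self.stage_2_plus:
            raise ValueError(
                "review intervals must strictly decrease with stage severity "
                f"(got 1a={self.stage_1a}, 1b={self.stage_1b}, 2+={self.stage_2_plus})"
            )
        return self

    def for_stage(self, stage: StageLabel) -> int:
        return {
            StageLabel.STAGE_1A: self.stage_1a,
            StageLabel.STAGE_1B: self.stage_1b,
            StageLabel.STAGE_2_PLUS: self.stage_2_plus,
        }[stage]


class RunConfig(BaseModel):
    """Complete engine configuration with published defaults."""

    model_config = ConfigDict(frozen=True)

    scale_cutoffs: dict[ScaleId, ScaleCutoffs] = Field(
        default_factory=lambda: {
            ScaleId.QIDS_SR16: ScaleCutoffs(moderate=11, severe=21),
            ScaleId.PHQ9: ScaleCutoffs(moderate=10, severe=20),
        }
    )
    depression: DepressionConfig = DepressionConfig()
    functioning: FunctioningEdges = FunctioningEdges()
    staging: StagingBranchConfig = StagingBranchConfig()
    review_intervals: ReviewIntervals = ReviewIntervals()
    # Reject records with unanswered items instead of scoring them as 0.
    require_complete: bool = False

    @model_validator(mode="after")
    def _fill_missing_scales(self) -> "RunConfig":
        # a partial YAML override of one scale keeps the others' defaults
        defaults = {
            ScaleId.QIDS_SR16: ScaleCutoffs(moderate=11, severe=21),
            ScaleId.PHQ9: ScaleCutoffs(moderate=10, severe=20),
        }
        for sid, cut in defaults.items():
            self.scale_cutoffs.setdefault(sid, cut)
        return self

    def cutoffs(self, scale_id: ScaleId) -> ScaleCutoffs:
        try:
            return self.scale_cutoffs[scale_id]
        except KeyError:
            raise KeyError(f"no cutoffs configured for scale {scale_id}") from None

    def config_hash(self) -> str:
        """Stable digest of the configuration, for run audit logs."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


DEFAULT_CONFIG = RunConfig()


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Load a YAML config file; missing keys fall back to defaults.

    With ``path=None`` returns the package defaults (identical to the
    shipped ``data/default_config.yaml``).
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def dump_default_config() -> str:
    """Render the default configuration as YAML."""
    return yaml.safe_dump(RunConfig().model_dump(mode="json"), sort_keys=False)


def shipped_default_config_text() -> str:
    return (resources.files("stagekit") / "data" / "default_config.yaml").read_text()
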