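"""Configuration models for the simulator, the rule engine, and the pipeline.

All calendars are integer days from a global origin (day 0); there is no
month or leap-year logic.  A patient's index day is day 0 of *follow-up*,
but claims tables carry absolute days.
"""

from __future__ import annotations

import hashlib
import json
import math
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from rxpatterns import drugs

# ---------------------------------------------------------------------------
# Simulator configuration
# ---------------------------------------------------------------------------

#: Cause-specific daily hazards per arm.  Defaults are calibrated so that the
#: 18-month (545-day) cumulative modification fractions and their split across
#: discontinuation / switching / intensification sit near the observed rates
#: in commercial-claims cohorts of these two drugs (overall modification
#: ~0.69 for the GLP-1 arm and ~0.76 for the basal-insulin arm).
DEFAULT_HAZARDS = {
    drugs.EXENATIDE: {
        "discontinue": 1.48e-3,
        "switch": 5.00e-4,
        "intensify": 5.05e-4,
    },
    drugs.GLARGINE: {
        "discontinue": 1.77e-3,
        "switch": 3.72e-4,
        "intensify": 9.75e-4,
    },
}

#: Log-odds weights on the propensity design columns (see
#: :func:`rxpatterns.match.propensity_design`) used to channel patients toward
#: the basal-insulin arm: older, sicker, hospitalised patients are more likely
#: to start insulin; endocrinology care channels toward the GLP-1 agonist.
DEFAULT_ASSIGNMENT = {
    "intercept": -0.95,
    "age_c": 0.45,
    "sex_female": -0.35,
    "macrovascular": 0.40,
    "microvascular": 0.15,
    "cci": 0.12,
    "inpatient_admission": 0.50,
    "log_cost_c": 0.10,
    "specialty_endocrinology": -0.70,
    "pre_sulfonylurea": 0.35,
    "pre_biguanide": -0.20,
}

DEFAULT_EXCLUSION_FRACTIONS = {
    "dx_type1": 0.015,
    "dx_gestational": 0.005,
    "dx_ckd": 0.015,
    "dx_cushing": 0.002,
    "dx_acromegaly": 0.002,
    "dx_gastric_surgery": 0.005,
    "glucocorticoid": 0.02,
    "washout_drug": 0.02,
    "enrollment_gap": 0.02,
    "rx_benefit_lapse": 0.01,
    "medicare_transition": 0.01,
    "under_18": 0.005,
}


class GapDistribution(BaseModel):
    """Distribution of slack days between run-out and the next fill."""

    kind: Literal["constant", "poisson"] = "poisson"
    value: int = 0  # constant slack
    mean: float = 2.0  # poisson mean
    cap: int = 14  # upper truncation, keeps slack far below the 90-day gap

    @field_validator("value", "cap")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("slack days must be non-negative")
        return v


class TitrationSchedule(BaseModel):
    """Per-refill dose multipliers for the basal-insulin arm.

    Ordinary titration multiplies the daily dose by Uniform(mult_low,
    mult_high) each refill (kept well below the escalation threshold);
    a true dose-escalation event applies ``escalation_mult`` once.
    ``dose_fraction`` is the share of that arm's intensification events
    realised as dose escalation rather than an added drug class.
    """

    mult_low: float = 1.0
    mult_high: float = 1.2
    escalation_mult: float = 3.0
    dose_fraction: float = 0.25
    start_dose_mean: float = 25.0
    start_dose_sd: float = 8.0
    dose_cap: float = 60.0

    @model_validator(mode="after")
    def _check(self) -> "TitrationSchedule":
        if not (0.0 <= self.dose_fraction <= 1.0):
            raise ValueError("dose_fraction must be in [0, 1]")
        if self.mult_low > self.mult_high:
            raise ValueError("mult_low > mult_high")
        return self


class SimConfig(BaseModel):
    """Parameters of the synthetic-claims generator."""

    n_patients: int = 4000
    #: absolute-day bounds (inclusive) of the index window; its length mirrors
    #: an 18-month enrolment window.
    index_window: tuple[int, int] = (400, 946)
    assignment_coefficients: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_ASSIGNMENT)
    )
    cause_specific_hazards: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {a: dict(h) for a, h in DEFAULT_HAZARDS.items()}
    )
    refill_gap_distribution: GapDistribution = Field(default_factory=GapDistribution)
    #: (days-supply, probability) choices for index-drug fills.
    days_supply_choices: list[tuple[int, float]] = Field(
        default_factory=lambda: [(30, 0.8), (90, 0.2)]
    )
    titration_schedule: TitrationSchedule = Field(default_factory=TitrationSchedule)
    exclusion_fractions: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_FRACTIONS)
    )
    follow_up_days: int = 545
    pre_index_days: int = 365
    gap_days: int = 90
    #: claims are emitted this many days past the follow-up horizon so that
    #: confirmation windows straddling day 545 are observable.
    emit_horizon_extra: int = 180
    seed: int = 0

    @field_validator("n_patients")
    @classmethod
    def _min_patients(cls, v: int) -> int:
        if v < 2:
            raise ValueError("n_patients must be >= 2")
        return v

    @field_validator("assignment_coefficients")
    @classmethod
    def _finite_coefs(cls, v: dict[str, float]) -> dict[str, float]:
        for name, c in v.items():
            if not math.isfinite(c):
                raise ValueError(f"non-finite assignment coefficient: {name}")
        return v

    @field_validator("cause_specific_hazards")
    @classmethod
    def _hazards_ok(cls, v: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
        for arm, causes in v.items():
            for cause, h in causes.items():
                if not math.isfinite(h) or h < 0:
                    raise ValueError(f"hazard must be finite and >= 0: {arm}/{cause}")
        return v

    @field_validator("exclusion_fractions")
    @classmethod
    def _fractions_ok(cls, v: dict[str, float]) -> dict[str, float]:
        for name, p in v.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"exclusion fraction out of [0,1]: {name}")
        return v

    @field_validator("days_supply_choices")
    @classmethod
    def _supplies_ok(cls, v: list[tuple[int, float]]) -> list[tuple[int, float]]:
        if not v or any(s <= 0 or p < 0 for s, p in v):
            raise ValueError("days_supply_choices must be positive supplies with p >= 0")
        total = sum(p for _, p in v)
        if total <= 0:
            raise ValueError("days_supply_choices probabilities sum to 0")
        return v

    @model_validator(mode="after")
    def _window_ok(self) -> "SimConfig":
        lo, hi = self.index_window
        if lo > hi:
            raise ValueError("index_window reversed")
        if lo < self.pre_index_days:
            raise ValueError("index_window must leave room for the pre-index window")
        return self

    def noiseless(self) -> "SimConfig":
        """Copy with zero refill slack (deterministic refill chains)."""
        cfg = self.model_copy(deep=True)
        cfg.refill_gap_distribution = GapDistribution(kind="constant", value=0)
        return cfg


# ---------------------------------------------------------------------------
# Rule-engine parameters
# ---------------------------------------------------------------------------


class ClassifyParams(BaseModel):
    """Tunable constants of the modification rules."""

    gap_days: int = 90  # permissible-gap length after a run-out
    follow_up_days: int = 545  # 18-month horizon (event days must not exceed it)
    pre_index_days: int = 365  # washout / baseline window length
    dose_threshold: float = 2.0  # claim-to-claim daily-dose ratio >= this escalates

    @model_validator(mode="after")
    def _positive(self) -> "ClassifyParams":
        if min(self.gap_days, self.follow_up_days, self.pre_index_days) <= 0:
            raise ValueError("windows must be positive")
        if self.dose_threshold <= 1.0:
            raise ValueError("dose_threshold must exceed 1.0")
        return self


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


class PipelineConfig(BaseModel):
    """End-to-end run configuration.

    Either ``simulate`` is set (synthetic inputs) or ``input_dir`` points at
    CSVs with the documented schemas.
    """

    simulate: Optional[SimConfig] = Field(default_factory=SimConfig)
    input_dir: Optional[str] = None
    classify_params: ClassifyParams = Field(default_factory=ClassifyParams)
    caliper_sd: float = 0.2  # caliper as a multiple of SD of the logit score
    cutoffs: list[int] = Field(default_factory=lambda: [180, 365, 545])
    cox_ties: Literal["breslow", "efron"] = "breslow"
    pair_stratified_cox: bool = False
    classify_full_cohort: bool = False  # sensitivity: classify before matching
    seed: int = 0
    output_dir: str = "rxpatterns_out"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.simulate is None and self.input_dir is None:
            raise ValueError("either simulate or input_dir must be given")
        cuts = self.cutoffs
        if any(c <= 0 for c in cuts) or sorted(cuts) != cuts:
            raise ValueError("cutoffs must be positive and ascending")
        if cuts and cuts[-1] > self.classify_params.follow_up_days:
            raise ValueError("cutoffs must not exceed the follow-up horizon")
        return self

    def config_hash(self) -> str:
        """Stable hash of every analysis-defining config field.

        The output directory is excluded: two runs of the same analysis into
        different directories share a fingerprint (and are byte-identical).
        """
        fields = self.model_dump(mode="json")
        fields.pop("output_dir", None)
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_pipeline_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
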