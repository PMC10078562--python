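"""Configuration models for simulation and analysis.

All user-facing configuration is a single JSON object with two optional
sections, ``simulation`` and ``analysis``.  Unknown keys are rejected
rather than ignored so that typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from pydantic import BaseModel, ConfigDict, Field, model_validator

AIR = "AIR"
CO2 = "CO2"
TIMEPOINTS = ("T5", "T10", "T15", "POST")
DURING_TIMEPOINTS = ("T5", "T10", "T15")


class ConfigError(ValueError):
    """Raised when a configuration file or object violates the schema."""


class SimulationConfig(BaseModel):
    """Parameters of the synthetic quiet-standing cohort.

    The defaults emulate the study design this package targets: 10
    subjects, two inhalation conditions (normal air vs 7.5% CO2-enriched
    air), centre-of-pressure (COP) trials collected at 5, 10 and 15 min of
    the inhalation period and once post-inhalation, five 30-s repetitions
    per time point.

    COP trials are generated per axis as a mean-reverting
    (Ornstein-Uhlenbeck) process, low-pass smoothed to emulate the
    mechanical filtering of the standing body, plus a variance-normalised
    chaotic (Lorenz) component; the OU diffusion sets the sway path
    length and the chaotic gain sets the local dynamic stability, so both
    study outcomes are independently tunable.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    n_subjects: int = Field(10, ge=1)
    inhalation_types: tuple[str, ...] = (AIR, CO2)
    timepoints: tuple[str, ...] = TIMEPOINTS
    reps_per_timepoint: int = Field(5, ge=1)
    trial_duration: float = Field(30.0, gt=0, description="seconds")
    cop_sampling_rate: float = Field(50.0, gt=0, description="Hz")
    ou_reversion: float = Field(1.0, gt=0, description="1/s")
    #: OU diffusion per condition, mm/sqrt(s); sets expected sway path.
    ou_noise_scale: dict[str, float] = {AIR: 5.0, CO2: 6.0}
    #: Corner (Hz) of the zero-phase low-pass applied to the stochastic
    #: baseline, emulating the mechanical low-pass of the standing body.
    cop_smoothing_hz: float = Field(0.3, gt=0)
    #: Amplitude (mm, standard deviation) of the chaotic blend per condition.
    chaos_blend_gain: dict[str, float] = {AIR: 1.5, CO2: 2.25}
    #: Log-normal sigma of the multiplicative between-subject effect.
    subject_sd: float = Field(0.2, ge=0)
    #: Mean breathing rate (breaths/min) keyed by (condition, phase).
    resp_rate_mean: dict[str, dict[str, float]] = {
        AIR: {"DURING": 12.1, "POST": 11.0},
        CO2: {"DURING": 15.0, "POST": 10.7},
    }
    resp_noise: float = Field(0.05, ge=0)
    resp_sampling_rate: float = Field(2000.0, gt=0, description="Hz")
    seed: int = 20221006

    @model_validator(mode="after")
    def _check_condition_keys(self) -> "SimulationConfig":
        for name in ("ou_noise_scale", "chaos_blend_gain", "resp_rate_mean"):
            mapping = getattr(self, name)
            missing = [t for t in self.inhalation_types if t not in mapping]
            if missing:
                raise ValueError(
                    f"{name} missing entries for inhalation types {missing}"
                )
        for cond, phases in self.resp_rate_mean.items():
            for phase in ("DURING", "POST"):
                if phase not in phases:
                    raise ValueError(
                        f"resp_rate_mean[{cond!r}] missing phase {phase!r}"
                    )
        if any(v < 0 for v in self.ou_noise_scale.values()):
            raise ValueError("ou_noise_scale values must be >= 0")
        if any(v < 0 for v in self.chaos_blend_gain.values()):
            raise ValueError("chaos_blend_gain values must be >= 0")
        return self

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.cop_sampling_rate))

    @property
    def n_trials(self) -> int:
        return (
            self.n_subjects
            * len(self.inhalation_types)
            * len(self.timepoints)
            * self.reps_per_timepoint
        )


class AnalysisSettings(BaseModel):
    """Settings of the analysis stages (embedding, LyE fit, respiration, stats)."""

    model_config = ConfigDict(extra="forbid")

    # nonlinear stability
    embedding_dimension: int = Field(6, ge=1)
    ami_max_lag: int = Field(150, ge=2)
    ami_n_bins: int = Field(64, ge=4)
    fit_window: tuple[float, float] = (0.0, 0.75)
    track_time: float = Field(1.0, gt=0, description="seconds")
    # respiration
    resp_target_rate: float = Field(100.0, gt=0)
    fir_low_cut: float = Field(0.5, gt=0)
    fir_high_cut: float = Field(1.0, gt=0)
    fir_n_coefficients: int = Field(8000, ge=2)
    fir_q_metadata: float = 0.70700  # vendor metadata, carried but unused
    br_baseline_window_ms: float = Field(25.0, gt=0)
    br_noise_rejection: float = Field(0.05, gt=0, lt=1)
    br_min_rate: float = Field(6.0, gt=0)
    br_max_rate: float = Field(20.0, gt=0)
    # statistics
    alpha: float = Field(0.05, gt=0, lt=1)
    outlier_z_cut: float = Field(2.5, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "AnalysisSettings":
        if not self.fir_low_cut < self.fir_high_cut:
            raise ValueError("fir_low_cut must be < fir_high_cut")
        if not self.br_min_rate < self.br_max_rate:
            raise ValueError("br_min_rate must be < br_max_rate")
        lo, hi = self.fit_window
        if not 0 <= lo < hi:
            raise ValueError("fit_window must satisfy 0 <= start < end")
        if self.track_time < hi:
            raise ValueError("track_time must cover the fit window")
        return self


class RunConfig(BaseModel):
    """Top-level configuration: one simulation and one analysis section."""

    model_config = ConfigDict(extra="forbid")

    simulation: SimulationConfig = SimulationConfig()
    analysis: AnalysisSettings = AnalysisSettings()


def load_config(path: str | Path | None = None, data: dict[str, Any] | None = None) -> RunConfig:
    """Load and validate a run configuration from a JSON file or dict.

    An empty object yields the full default configuration.  Unknown keys
    anywhere in the object raise :class:`ConfigError` listing the offending
    locations.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            try:
                data = json.loads(Path(path).read_text())
            except json.JSONDecodeError as exc:
                raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a JSON object")
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(str(exc)) from exc


def dump_config(config: RunConfig) -> str:
    """Serialise a configuration to canonical JSON (load∘dump idempotent)."""
    return json.dumps(config.model_dump(mode="json"), indent=2, sort_keys=True)
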