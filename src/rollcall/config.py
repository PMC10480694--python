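"""Pipeline configuration: one validated document for every knob.

All thresholds and conventions that affect results are surfaced here;
there are no hidden defaults on code paths that change numbers.  The
schema is a pydantic model, so a YAML config is validated before any
computation starts.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator


class DetectionConfig(BaseModel):
    window_s: float = 2.0
    mean_thresh_g: float = 0.0
    sd_thresh_g: float = 1.4
    min_gap_s: float = 10.0
    min_duration_s: float = 0.5


class RollConfig(BaseModel):
    convention: Literal["half_range", "full_range"] = "half_range"
    predive_window_s: float = 5.0
    circular_mean: bool = False


class LateralityConfig(BaseModel):
    threshold: float = 0.25
    min_dives: int = 5


class RepeatabilityConfig(BaseModel):
    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 1
    #: include the bird-level laterality class as a fixed effect in a
    #: second roll-angle model (three fits total when True)
    laterality_state_fixed: bool = True


class SimulationConfig(BaseModel):
    n_birds: int = 51
    days_per_bird: Tuple[int, int] = (1, 6)
    dives_per_bird_day: float = 13.0
    season_days: int = 30
    var_id_logit: float = 34.0
    var_date_logit: float = 1.4
    mu_angle_deg: float = 25.0
    var_id_angle: float = 144.0
    var_resid_angle: float = 49.0
    seed: int = 0


class InputConfig(BaseModel):
    """Either raw trace CSVs on disk or a simulation block."""

    trace_csvs: List[Path] = Field(default_factory=list)
    time_column: str = "time"
    axis_columns: Tuple[str, str, str] = ("ax", "ay", "az")
    units: Literal["g", "ms2"] = "g"
    rate_hz: float = 50.0
    simulate: Optional[SimulationConfig] = None

    @model_validator(mode="after")
    def _one_source(self):
        if bool(self.trace_csvs) == (self.simulate is not None):
            raise ValueError("configure exactly one of trace_csvs or simulate")
        return self


class PipelineConfig(BaseModel):
    input: InputConfig
    detection: DetectionConfig = DetectionConfig()
    roll: RollConfig = RollConfig()
    laterality: LateralityConfig = LateralityConfig()
    repeatability: RepeatabilityConfig = RepeatabilityConfig()
    output_dir: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)
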