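"""Pipeline configuration: YAML-backed, with the field-standard defaults.

Omitted keys fall back to the study defaults (segmentation threshold 0.02,
CFI threshold 150, PAR = 45% of solar radiation, GDD base 15.6 °C and cap
33.9 °C, 60/40 train/validation split, IQR outlier factor 1.5). Unknown
keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from cottonphys.exceptions import ConfigError


@dataclass
class PipelineConfig:
    # input/output paths (None → synthetic study generated in memory)
    weather_path: str | None = None
    rasters_dir: str | None = None
    rois_path: str | None = None
    ground_path: str | None = None
    harvest_dir: str | None = None
    harvest_rois_path: str | None = None
    out_dir: str | None = None
    planting_date: str | None = None  # ISO date, required for on-disk inputs
    season: str = "season-1"

    # thresholds
    segmentation_threshold: float = 0.02
    cfi_threshold: int = 150

    # model settings
    model_terms: str = "full"  # "full" (VI, GDD, VI×GDD) or "main"
    train_fraction: float = 0.6
    seed: int = 0
    outlier_factor: float = 1.5

    # physical constants
    par_fraction: float = 0.45
    base_temp_c: float = 15.6
    ceiling_temp_c: float = 33.9

    # synthetic mode
    synthetic: bool = True
    sim_seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if not 0.0 < self.par_fraction < 1.0:
            raise ConfigError("par_fraction must lie in (0, 1)")
        if self.model_terms not in ("full", "main"):
            raise ConfigError("model_terms must be 'full' or 'main'")


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a YAML mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
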