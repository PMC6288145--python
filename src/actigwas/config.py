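"""Pipeline-wide configuration.

All thresholds used across the pipeline live in one dataclass so that a
single YAML file (or a single object) fully determines a run.  Defaults are
the values used throughout the analysis: 30-s epochs, 100 Hz sampling,
60-min non-wear rule, 13 mg stationarity threshold, 100 mg implausible-value
cut, 72 h minimum wear, genome-wide significance at 5e-9, +/-400 kb locus
windows, and the MR instrument-selection thresholds (p < 5e-6, r^2 < 0.001,
> 10,000 kb separation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    # epoching / preprocessing
    epoch_s: float = 30.0
    sample_rate: float = 100.0          # Hz
    stationary_sd_mg: float = 13.0      # per-axis SD below which a window is stationary
    stationary_window_s: float = 10.0   # window length used for calibration stationarity
    calib_residual_max_mg: float = 10.0
    calib_min_stationary: int = 10
    # non-wear / QC
    nonwear_min: float = 60.0           # minutes of continuous stationarity
    clipped_fraction_max: float = 0.01
    enmo_max_mg: float = 100.0
    min_wear_h: float = 72.0
    # GWAS post-processing
    gws_p: float = 5e-9
    conventional_p: float = 5e-8
    locus_half_kb: float = 400.0
    maf_min: float = 0.001
    info_min: float = 0.3
    hwe_p: float = 1e-7
    # MR instrument selection
    instrument_p: float = 5e-6
    instrument_r2: float = 0.001
    instrument_dist_kb: float = 10000.0
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and f.name != "seed" and v <= 0:
                raise ValueError(f"config field {f.name!r} must be positive, got {v}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def header_lines(self) -> list[str]:
        """Config serialised as '# cfg key=value' comment lines for output provenance."""
        return [f"# cfg {k}={v}" for k, v in self.to_dict().items()]


DEFAULT_CONFIG = PipelineConfig()
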