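"""Plain-text interchange formats.

All tables are UTF-8 TSV with '.' decimals and 'NA' for missing values; raw
acceleration travels as CSV with columns ``time_s, x_g, y_g, z_g``.  Writers
can prepend '# cfg key=value' provenance comment lines (the full pipeline
configuration); readers skip '#' comments, so every writer/reader pair
round-trips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .preprocess import RawRecording

__all__ = [
    "write_raw_csv", "read_raw_csv",
    "write_table", "read_table",
    "write_truth_tsv",
]

_NA = "NA"


def _header(config: PipelineConfig | None) -> str:
    return ("\n".join(config.header_lines()) + "\n") if config is not None else ""


def write_raw_csv(raw: RawRecording, path: str | Path,
                  config: PipelineConfig | None = None) -> None:
    df = pd.DataFrame({
        "time_s": raw.times,
        "x_g": raw.accel[:, 0],
        "y_g": raw.accel[:, 1],
        "z_g": raw.accel[:, 2],
    })
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write(f"# clip_limit_g={raw.clip_limit}\n# t0_clock_s={raw.t0_clock_s}\n")
        df.to_csv(fh, index=False, na_rep=_NA)


def read_raw_csv(path: str | Path) -> RawRecording:
    clip_limit, t0 = 8.0, 0.0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# clip_limit_g="):
                clip_limit = float(line.split("=", 1)[1])
            elif line.startswith("# t0_clock_s="):
                t0 = float(line.split("=", 1)[1])
    df = pd.read_csv(path, comment="#", na_values=[_NA])
    need = {"time_s", "x_g", "y_g", "z_g"}
    if not need.issubset(df.columns):
        raise ValueError(f"raw CSV missing columns: {sorted(need - set(df.columns))}")
    return RawRecording(df["time_s"].to_numpy(float),
                        df[["x_g", "y_g", "z_g"]].to_numpy(float),
                        clip_limit, t0)


def write_table(df: pd.DataFrame, path: str | Path,
                config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, na_rep=_NA)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[_NA])


def write_truth_tsv(truth, path: str | Path) -> None:
    """Epoch-level ground truth sidecar for a simulated recording."""
    from .classifier import STATES

    df = pd.DataFrame({
        "epoch": np.arange(truth.state_sequence.size),
        "state": [STATES[s] for s in truth.state_sequence],
        "nonwear": truth.nonwear_mask.astype(int),
    })
    write_table(df, path)
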