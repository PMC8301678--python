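"""CSV/YAML input-output with validation.

Column dictionary (all plain CSV):

* individuals: ``sample_id, set, q, morphotype`` (+ optional ``length_mm``,
  ``species``, ``individual_id``); ``q`` in [0, 1]; morphotype normalised to
  upper-case T/E.
* sample metadata: ``sample_id, set, salinity_class, true_ptros, n``.
* sample summaries: the output of :func:`morphotest.metrics.summaries_frame`.

Validation failures raise :class:`DataError` naming the offending rows
(1-based CSV data rows); configuration problems raise :class:`ConfigError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

PathLike = Union[str, Path]

__all__ = [
    "DataError",
    "ConfigError",
    "PipelineConfig",
    "read_individuals",
    "write_individuals",
    "read_sample_metadata",
    "read_summaries",
    "write_summaries",
    "read_config",
]


class DataError(ValueError):
    """Malformed input data (exit code 1 in the CLI)."""


class ConfigError(ValueError):
    """Malformed configuration (exit code 2 in the CLI)."""


REQUIRED_INDIVIDUAL_COLUMNS = ("sample_id", "set", "q", "morphotype")


def _rows(mask: np.ndarray, limit: int = 8) -> str:
    rows = (np.flatnonzero(mask) + 2).tolist()  # +2: header + 1-based
    shown = ", ".join(map(str, rows[:limit]))
    more = "" if len(rows) <= limit else f" (+{len(rows) - limit} more)"
    return shown + more


def read_individuals(path: PathLike) -> pd.DataFrame:
    """Read and validate an individual-level CSV."""
    df = pd.read_csv(path)
    missing = set(REQUIRED_INDIVIDUAL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required columns {sorted(missing)}")
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")
    q = pd.to_numeric(df["q"], errors="coerce")
    bad_q = ~((q >= 0.0) & (q <= 1.0))
    if bad_q.any():
        raise DataError(f"{path}: q outside [0, 1] (or non-numeric) at rows {_rows(bad_q.to_numpy())}")
    df["q"] = q
    morph = df["morphotype"].astype(str).str.strip().str.upper()
    bad_m = ~morph.isin(["T", "E"])
    if bad_m.any():
        raise DataError(
            f"{path}: unknown morphotype codes at rows {_rows(bad_m.to_numpy())} "
            f"(expected T or E)"
        )
    df["morphotype"] = morph
    if "length_mm" in df.columns:
        length = pd.to_numeric(df["length_mm"], errors="coerce")
        bad_l = length.notna() & (length <= 0.0)
        if bad_l.any():
            raise DataError(f"{path}: non-positive length_mm at rows {_rows(bad_l.to_numpy())}")
        df["length_mm"] = length
    if "individual_id" in df.columns:
        dup = df["individual_id"].duplicated(keep=False)
        if dup.any():
            raise DataError(f"{path}: duplicate individual ids at rows {_rows(dup.to_numpy())}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["set"] = df["set"].astype(str)
    return df


def write_individuals(df: pd.DataFrame, path: PathLike) -> None:
    cols = [c for c in ("sample_id", "set", "species", "q", "morphotype", "length_mm") if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_sample_metadata(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: sample metadata must contain a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_summaries(summaries_df: pd.DataFrame, path: PathLike) -> None:
    summaries_df.to_csv(path, index=False)


def read_summaries(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"sample_id", "n_T_tros", "n_E_tros", "n_T_edu", "n_E_edu"}
    missing = needed - set(df.columns)
    if missing:
        raise DataError(f"{path}: summary CSV missing columns {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (read from a key-value YAML file)."""

    individuals: Optional[str] = None
    output_dir: str = "morphotest_out"
    q_threshold: float = 0.5
    pure_low: float = 0.1
    pure_high: float = 0.8
    mixed_low: float = 0.45
    mixed_high: float = 0.65
    grid_step: float = 0.01
    loess_span: float = 0.75
    seed: int = 0
    simulate: Optional[dict] = None  # forwarded to SimulationConfig when set

    def __post_init__(self) -> None:
        bounds = (self.q_threshold, self.pure_low, self.pure_high, self.mixed_low, self.mixed_high)
        if any(not 0.0 <= b <= 1.0 for b in bounds):
            raise ConfigError("thresholds must lie in [0, 1]")
        if not self.pure_low < self.pure_high:
            raise ConfigError("pure-stratum bounds must be ordered (low < high)")
        if not self.mixed_low < self.mixed_high:
            raise ConfigError("mixed-stratum bounds must be ordered (low < high)")
        if not 0.0 < self.grid_step <= 0.5:
            raise ConfigError("grid_step must lie in (0, 0.5]")
        if self.individuals is None and self.simulate is None:
            raise ConfigError("config must provide either 'individuals' or 'simulate'")


def read_config(path: PathLike) -> PipelineConfig:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)
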