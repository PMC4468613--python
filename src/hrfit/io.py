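"""Readers/writers and run configuration for the fitting pipeline.

File conventions: comma-separated, UTF-8, mandatory header row of channel
ids, '.' decimal separator; a time column is optional (the grid is derived
from the sampling rate).  Configs and manifests are YAML/JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hrf import Paradigm, default_bounds
from .simplex import NMConfig

__all__ = [
    "TimeSeriesParseError",
    "read_timeseries",
    "write_timeseries",
    "read_layout",
    "RunConfig",
]


class TimeSeriesParseError(ValueError):
    """A series file failed validation; the message names the offending cell."""


def read_timeseries(
    path, time_column: str | None = "time", drop_time: bool = True
) -> pd.DataFrame:
    """Read a wide CSV/TSV of channel series, validating every cell.

    Columns are channel ids; rows are samples.  Lines starting with '#' are
    treated as provenance comments.  NaN or non-numeric cells raise
    :class:`TimeSeriesParseError` naming the row and column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise TimeSeriesParseError(f"{path}: malformed table: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise TimeSeriesParseError(f"{path}: empty table")
    if drop_time and time_column is not None and time_column in df.columns:
        df = df.drop(columns=[time_column])
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TimeSeriesParseError(
                f"{path}: non-numeric or missing value at row {row + 2} "
                f"(1-based, incl. header), column '{col}': {df[col].iloc[row]!r}"
            )
        df[col] = numeric.astype(float)
    return df


def write_timeseries(
    df: pd.DataFrame, path, fs: float | None = None, provenance: str | None = None
) -> None:
    """Write a wide channel-series CSV with '#' provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# written by hrfit\n")
        if fs is not None:
            fh.write(f"# fs_hz: {fs}\n")
        if provenance:
            for line in provenance.splitlines():
                fh.write(f"# {line}\n")
        # default float formatting is repr-based: round-trips exactly
        df.to_csv(fh, index=False)


def read_layout(path) -> pd.DataFrame:
    """Read a channel layout CSV with columns channel_id, grid_row, grid_col."""
    df = pd.read_csv(path, comment="#")
    required = {"channel_id", "grid_row", "grid_col"}
    missing = required - set(df.columns)
    if missing:
        raise TimeSeriesParseError(
            f"{path}: layout is missing columns {sorted(missing)}"
        )
    return df


@dataclass
class RunConfig:
    """Validated end-to-end run configuration with paper-traceable defaults."""

    fs: float = 1.81
    rest_pre: float = 10.0
    task: float = 10.0
    rest_post: float = 30.0
    n_trials: int = 1
    noise_sd: float = 0.2
    alpha: float = 0.05
    seed: int = 0
    n_restarts: int = 10
    max_iter: int = 5000
    tol_x: float = 1e-6
    tol_f: float = 1e-10
    simplex_size: float = 0.1
    dpf_l1: float = 7.25
    dpf_l2: float = 6.38
    separation: float = 3.0
    layout_path: str | None = None
    output_dir: str = "hrfit_output"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        # constructing these validates the remaining fields
        self.paradigm()
        self.nm_config()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = (
                json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
            )
        data = data or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def paradigm(self) -> Paradigm:
        return Paradigm(
            fs=self.fs,
            rest_pre=self.rest_pre,
            task=self.task,
            rest_post=self.rest_post,
            n_trials=self.n_trials,
        )

    def nm_config(self) -> NMConfig:
        return NMConfig(
            simplex_size=self.simplex_size,
            max_iter=self.max_iter,
            tol_x=self.tol_x,
            tol_f=self.tol_f,
            n_restarts=self.n_restarts,
            seed=self.seed,
        )

    def to_record(self) -> dict:
        from . import __version__

        return {"config": asdict(self), "package_version": __version__,
                "bounds": default_bounds().tolist()}
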