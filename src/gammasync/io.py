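"""Delimited-text readers/writers and the run configuration.

File conventions: comma-separated matrices with one header row of
channel labels; all sample indices in files are 1-based inclusive
(internally everything is 0-based). The run configuration is one flat
YAML document validated against a fixed schema; unknown keys are
errors, because a silently ignored typo in ``w`` or the band would
corrupt the science downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .ic import CLIP_CEIL, CLIP_FLOOR, ICSeries
from .mixture import MixtureFit, StateSequence
from .preprocess import CyclePartition, RawEpoch

__all__ = [
    "RunConfig",
    "read_epoch",
    "write_signals",
    "write_partition",
    "read_partition",
    "write_ic_series",
    "read_ic_series",
    "write_fit",
    "write_bic_table",
    "write_states",
]


@dataclass
class RunConfig:
    """All pipeline settings, serializable to/from YAML."""

    sample_rate: float = 1500.0
    band_low: float = 40.0
    band_high: float = 100.0
    base_channel: str = ""
    w: int = 6
    m: int = 2
    p_min: int = 2
    p_max: int = 8
    alpha: float = 0.05
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 500
    clip_floor: float = CLIP_FLOOR
    clip_ceil: float = CLIP_CEIL

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if not (0 < self.band_low < self.band_high < self.sample_rate / 2):
            raise ConfigError(
                f"band ({self.band_low}, {self.band_high}) must lie inside "
                f"(0, {self.sample_rate / 2}) and be ordered"
            )
        if not (1 <= self.m < self.w):
            raise ConfigError(f"need 1 <= m < w, got w={self.w}, m={self.m}")
        if not (1 <= self.p_min <= self.p_max):
            raise ConfigError("need 1 <= p_min <= p_max")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if not (0 < self.clip_floor < self.clip_ceil < 1):
            raise ConfigError("clip limits must satisfy 0 < floor < ceil < 1")

    @property
    def p_range(self) -> range:
        return range(self.p_min, self.p_max + 1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError("config file must hold a key-value mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def read_epoch(path: str | Path, rate: float) -> RawEpoch:
    """Read a samples-by-channels CSV (header row of channel labels)."""
    df = pd.read_csv(path)
    return RawEpoch(
        samples=df.to_numpy(dtype=float),
        rate=rate,
        channel_labels=[str(c) for c in df.columns],
    )


def write_signals(path: str | Path, signals: list, labels: list[str] | None = None) -> None:
    """Write filtered channels in the same samples-by-channels layout."""
    labels = labels or [s.label or f"ch{i + 1}" for i, s in enumerate(signals)]
    df = pd.DataFrame({lab: s.values for lab, s in zip(labels, signals)})
    df.to_csv(path, index=False)


def write_partition(path: str | Path, partition: CyclePartition) -> None:
    """Single-column file of 1-based boundary sample indices."""
    pd.DataFrame({"boundary_sample": partition.boundaries + 1}).to_csv(path, index=False)


def read_partition(path: str | Path) -> CyclePartition:
    df = pd.read_csv(path)
    return CyclePartition(boundaries=df["boundary_sample"].to_numpy(dtype=int) - 1)


def _ic_frame(series: ICSeries, ci=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "window_index": np.arange(1, series.n_windows + 1),
            "start_sample": series.windows[:, 0] + 1,
            "end_sample": series.windows[:, 1] + 1,
        }
    )
    for j, lab in enumerate(series.channel_labels):
        df[lab] = series.U[:, j]
        if ci is not None:
            lower, upper = ci
            df[f"{lab}_lower"] = lower[:, j]
            df[f"{lab}_upper"] = upper[:, j]
    return df


def write_ic_series(path: str | Path, series: ICSeries, ci=None) -> None:
    """IC series as CSV: window_index, start/end samples (1-based), one
    IC column per channel, optionally flanked by CI columns."""
    _ic_frame(series, ci).to_csv(path, index=False)


def read_ic_series(path: str | Path) -> ICSeries:
    df = pd.read_csv(path)
    meta = {"window_index", "start_sample", "end_sample"}
    channels = [
        c for c in df.columns if c not in meta and not c.endswith(("_lower", "_upper"))
    ]
    windows = np.column_stack(
        [df["start_sample"].to_numpy(int) - 1, df["end_sample"].to_numpy(int) - 1]
    )
    U = df[channels].to_numpy(dtype=float)
    return ICSeries(
        windows=windows,
        U=U,
        lags=np.zeros_like(U, dtype=int),
        channel_labels=channels,
    )


def write_fit(path: str | Path, fit: MixtureFit) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def write_bic_table(path: str | Path, fits_bics: dict, logliks: dict | None = None) -> None:
    rows = [
        {"p": p, "loglik": logliks.get(p) if logliks else None, "bic": b}
        for p, b in sorted(fits_bics.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_states(path: str | Path, seq: StateSequence) -> None:
    """State sequence with window boundaries so states map back to time."""
    n = seq.states.size
    windows = seq.windows if seq.windows is not None else np.zeros((n, 2), dtype=int) - 1
    pd.DataFrame(
        {
            "window_index": np.arange(1, n + 1),
            "start_sample": windows[:, 0] + 1,
            "end_sample": windows[:, 1] + 1,
            "state": seq.states,
        }
    ).to_csv(path, index=False)
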