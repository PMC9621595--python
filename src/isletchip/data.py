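"""Measurement time-series container and its delimited-text format.

A :class:`TimeSeriesDataset` is the unit of calibration: a tidy table of
mean +/- SEM measurement points with one row per (series, time), where a
series is identified by observable, culture type, glycemic regime and GTT
tag.  Datasets round-trip through plain CSV with the columns
``series_id, observable, culture_type, regime, gtt, time_h, mean, sem, n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesDataset", "correct_sem"]

COLUMNS = ["series_id", "observable", "culture_type", "regime", "gtt",
           "time_h", "mean", "sem", "n"]


@dataclass
class TimeSeriesDataset:
    """Observed or synthetic mean +/- SEM measurement series."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset table missing columns {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("dataset is empty")
        t = self.table
        if (t["sem"] < 0).any():
            raise ValueError("sem values must be nonnegative")
        if (t["n"] < 1).any():
            raise ValueError("replicate counts must be >= 1")
        self.table = t[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_points(self) -> int:
        return len(self.table)

    def conditions(self) -> list[tuple[str, str]]:
        """Unique (culture_type, regime) pairs, in stable order."""
        seen = []
        for ct, rg in zip(self.table["culture_type"], self.table["regime"]):
            if (ct, rg) not in seen:
                seen.append((ct, rg))
        return seen

    def gtt_days(self, culture_type: str, regime: str) -> tuple[int, ...]:
        sub = self.table[(self.table["culture_type"] == culture_type)
                         & (self.table["regime"] == regime)]
        days = sorted({1 if g == "d1" else 13 for g in sub["gtt"]})
        return tuple(days)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "TimeSeriesDataset":
        return cls(pd.read_csv(path))


def correct_sem(dataset: TimeSeriesDataset,
                floor_fraction: float = 0.05,
                fallback_fraction: float = 0.10) -> TimeSeriesDataset:
    """Correct under-estimated SEM values from small replicate counts.

    With few replicate platforms the sample SEM can be unrealistically
    small.  Points whose SEM is below ``floor_fraction`` (5%) of their mean
    are assigned the largest measured SEM across the whole dataset; when
    every point falls below the floor, all SEMs are set to
    ``fallback_fraction`` (10%) of their means instead.
    """
    t = dataset.table.copy()
    if (t["mean"] <= 0).any():
        raise ValueError("SEM correction requires positive means")
    low = t["sem"] < floor_fraction * t["mean"]
    if low.all():
        t["sem"] = fallback_fraction * t["mean"]
    elif low.any():
        t.loc[low, "sem"] = t["sem"].max()
    return TimeSeriesDataset(t)
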