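"""Core containers for fixed-interval temperature logger records.

A :class:`TemperatureSeries` is one site's record on a strictly regular
time grid (default 20-min sampling, 72 samples per day). Gaps are explicit
``NaN`` values on the grid — they are never interpolated. Timestamps are
naive local time; day boundaries fall at local midnight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SiteMeta", "TemperatureSeries", "SmoothedSeries"]


@dataclass(frozen=True)
class SiteMeta:
    """Site identity and location.

    Longitude is stored in positive-west decimal degrees (the convention
    used for eastern-Pacific / Gulf of California site tables).
    """

    site_id: int
    name: str
    lat: float
    lon: float
    depth_m: float = 5.0


@dataclass
class TemperatureSeries:
    """Regular-grid temperature record (°C) with site metadata.

    Parameters
    ----------
    meta
        Site identity.
    data
        ``pd.Series`` of temperatures indexed by a strictly increasing,
        constant-spacing naive ``DatetimeIndex``. ``NaN`` marks missing
        samples.
    """

    meta: SiteMeta
    data: pd.Series

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("TemperatureSeries requires a DatetimeIndex")
        if len(idx) < 1:
            raise ValueError("empty temperature series")
        if idx.tz is not None:
            raise ValueError("timestamps must be naive local time")
        if len(idx) > 1:
            diffs = np.diff(idx.asi8)
            if np.any(diffs <= 0):
                bad = idx[1:][diffs <= 0][0]
                raise ValueError(
                    f"timestamps not strictly increasing at {bad}"
                )
            if len(np.unique(diffs)) != 1:
                raise ValueError("non-constant sampling interval")
        self.data = self.data.astype(float)

    # -- grid geometry -------------------------------------------------

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def temps(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def interval_minutes(self) -> float:
        if len(self.data) < 2:
            raise ValueError("interval undefined for a single sample")
        return float(np.diff(self.data.index.asi8[:2])[0] / 60e9)

    @property
    def samples_per_day(self) -> int:
        return int(round(1440.0 / self.interval_minutes))

    @property
    def n_valid(self) -> int:
        return int(self.data.notna().sum())

    def __len__(self) -> int:
        return len(self.data)

    def with_values(self, values: np.ndarray) -> "TemperatureSeries":
        """Same grid and metadata, new temperatures."""
        return replace(
            self, data=pd.Series(values, index=self.data.index, dtype=float)
        )


@dataclass
class SmoothedSeries:
    """Centered running mean aligned to the parent series' grid.

    ``running_mean`` is ``NaN`` wherever the window's ``coverage``
    (fraction of the nominal window populated with valid samples) falls
    below the threshold used at construction.
    """

    timestamps: pd.DatetimeIndex
    running_mean: np.ndarray
    window_days: int
    coverage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.window_days % 2 == 0:
            raise ValueError("window_days must be odd")
        if len(self.timestamps) != len(self.running_mean):
            raise ValueError("running_mean misaligned with timestamps")

    def as_series(self) -> pd.Series:
        return pd.Series(self.running_mean, index=self.timestamps)
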