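"""Logger ingestion, paired-logger merging, running means, daily and
site summaries, and seasonal splitting.

Seasons follow the subtropical convention used throughout the analysis:
summer is May–October, winter is November–April. The 29-day centered
running mean is the low-frequency reference from which cooling anomalies
are measured.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import SiteMeta, SmoothedSeries, TemperatureSeries

__all__ = [
    "SiteSummary",
    "SUMMER_MONTHS",
    "read_logger_csv",
    "write_logger_csv",
    "read_site_metadata",
    "write_site_metadata",
    "merge_paired_loggers",
    "running_mean",
    "daily_summaries",
    "seasonal_split",
    "site_summary",
    "site_summary_table",
    "single_day_range_fraction",
]

#: Months assigned to the summer (high-variability) season.
SUMMER_MONTHS = frozenset({5, 6, 7, 8, 9, 10})


@dataclass(frozen=True)
class SiteSummary:
    """Whole-record summary statistics for one site (sample stdev)."""

    site_id: int
    site_name: str
    lat: float
    lon: float
    mean: float
    min: float
    max: float
    range: float
    stdev: float


# ---------------------------------------------------------------------
# I/O


def read_site_metadata(path: str | Path) -> SiteMeta:
    """Read a sidecar JSON/YAML site-metadata file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SiteMeta(
        site_id=int(raw["site_id"]),
        name=str(raw["name"]),
        lat=float(raw["lat"]),
        lon=float(raw["lon"]),
        depth_m=float(raw.get("depth_m", 5.0)),
    )


def write_site_metadata(meta: SiteMeta, path: str | Path) -> None:
    payload = {
        "site_id": meta.site_id,
        "name": meta.name,
        "lat": meta.lat,
        "lon": meta.lon,
        "depth_m": meta.depth_m,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_logger_csv(
    path: str | Path, meta: SiteMeta | None = None
) -> TemperatureSeries:
    """Read one logger record (columns ``timestamp``, ``temp_c``).

    If ``meta`` is not given, a ``<stem>.meta.json`` sidecar next to the
    CSV is used when present; otherwise placeholder metadata is attached.
    Out-of-order rows, duplicated timestamps and irregular sampling are
    rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "timestamp" not in df.columns or "temp_c" not in df.columns:
        raise ValueError(f"{path}: expected columns 'timestamp', 'temp_c'")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(
            f"{path}: malformed timestamp at data row {row}: "
            f"{df['timestamp'].iloc[row]!r}"
        )
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated timestamp {dup}")
    if not ts.is_monotonic_increasing:
        raise ValueError(f"{path}: timestamps out of order")
    if meta is None:
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            meta = read_site_metadata(sidecar)
        else:
            meta = SiteMeta(site_id=0, name=path.stem, lat=np.nan, lon=np.nan)
    data = pd.Series(
        df["temp_c"].to_numpy(dtype=float), index=pd.DatetimeIndex(ts)
    )
    return TemperatureSeries(meta=meta, data=data)


def write_logger_csv(series: TemperatureSeries, path: str | Path) -> None:
    """Write a logger CSV (ISO-8601 timestamps, full-precision temps)."""
    out = pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "temp_c": series.temps,
        }
    )
    # shortest round-trip repr preserves float64 values exactly
    out.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------
# Merging and smoothing


def merge_paired_loggers(
    a: TemperatureSeries, b: TemperatureSeries
) -> TemperatureSeries:
    """Mean of two redundant loggers at each shared time point.

    Where only one logger has a value, that value is used unchanged
    (single-logger fallback); where both are missing the sample stays
    missing. The two records must belong to the same site and overlap in
    time.
    """
    if a.meta.site_id != b.meta.site_id:
        raise ValueError(
            f"cannot merge loggers from different sites "
            f"({a.meta.site_id} vs {b.meta.site_id})"
        )
    if len(a.timestamps.intersection(b.timestamps)) == 0:
        raise ValueError("paired loggers share no timestamps")
    idx = a.timestamps.union(b.timestamps)
    stacked = pd.DataFrame(
        {"a": a.data.reindex(idx), "b": b.data.reindex(idx)}
    )
    merged = stacked.mean(axis=1)  # skips NaN: single-logger fallback
    return TemperatureSeries(meta=a.meta, data=merged)


def running_mean(
    series: TemperatureSeries,
    window_days: int = 29,
    min_coverage: float = 0.9,
) -> SmoothedSeries:
    """Centered running mean over ``window_days`` (odd), on the raw grid.

    The window at each sample spans ±``window_days``/2 days inclusive.
    Samples whose window coverage (valid-sample fraction of the nominal
    window length) is below ``min_coverage`` — record edges, large gaps —
    get a missing running mean.
    """
    if window_days % 2 == 0:
        raise ValueError(f"window_days must be odd, got {window_days}")
    spd = series.samples_per_day
    span_days = (
        series.timestamps[-1] - series.timestamps[0]
    ) / pd.Timedelta(days=1)
    if span_days < window_days:
        raise ValueError(
            f"series spans {span_days:.1f} days; "
            f"need at least {window_days}"
        )
    n_win = window_days * spd + 1  # inclusive of both half-window ends
    roll = series.data.rolling(n_win, center=True, min_periods=1)
    mean = roll.mean().to_numpy()
    coverage = (roll.count().to_numpy() / n_win).astype(float)
    mean[coverage < min_coverage] = np.nan
    return SmoothedSeries(
        timestamps=series.timestamps,
        running_mean=mean,
        window_days=window_days,
        coverage=coverage,
    )


# ---------------------------------------------------------------------
# Summaries


def daily_summaries(series: TemperatureSeries) -> pd.DataFrame:
    """Per-calendar-day min/max/mean/std (sample stdev) and sample count.

    Days with no valid samples are omitted; a single-sample day has an
    undefined (NaN) stdev.
    """
    valid = series.data.dropna()
    if valid.empty:
        raise ValueError("no valid samples")
    grouped = valid.groupby(valid.index.normalize())
    out = grouped.agg(["min", "max", "mean", "std", "count"])
    out.columns = ["min", "max", "mean", "std", "n_samples"]
    out.index.name = "date"
    return out.reset_index()


def seasonal_split(
    series: TemperatureSeries,
) -> tuple[TemperatureSeries, TemperatureSeries]:
    """Split into summer (May–Oct) and winter (Nov–Apr) on the full grid.

    Each output keeps the parent's regular grid with the other season's
    samples masked to missing, so the two halves partition the valid
    samples exactly and remain usable by segment-based spectral analysis.
    """
    in_summer = series.timestamps.month.isin(sorted(SUMMER_MONTHS))
    summer_vals = np.where(in_summer, series.temps, np.nan)
    winter_vals = np.where(in_summer, np.nan, series.temps)
    return series.with_values(summer_vals), series.with_values(winter_vals)


def site_summary(series: TemperatureSeries) -> SiteSummary:
    """Whole-record Mean/Min/Max/Range/Stdev for one site."""
    valid = series.data.dropna()
    if valid.empty:
        raise ValueError("no valid samples")
    lo, hi = float(valid.min()), float(valid.max())
    return SiteSummary(
        site_id=series.meta.site_id,
        site_name=series.meta.name,
        lat=series.meta.lat,
        lon=series.meta.lon,
        mean=float(valid.mean()),
        min=lo,
        max=hi,
        range=hi - lo,
        stdev=float(valid.std(ddof=1)) if len(valid) > 1 else 0.0,
    )


def site_summary_table(series_list: list[TemperatureSeries]) -> pd.DataFrame:
    """Site-by-site summary table (one row per site, north-style schema)."""
    rows = [site_summary(s) for s in series_list]
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in rows],
            "site_name": [r.site_name for r in rows],
            "lat": [r.lat for r in rows],
            "lon": [r.lon for r in rows],
            "mean": [r.mean for r in rows],
            "min": [r.min for r in rows],
            "max": [r.max for r in rows],
            "range": [r.range for r in rows],
            "stdev": [r.stdev for r in rows],
        }
    )


def single_day_range_fraction(
    series: TemperatureSeries,
) -> tuple[float, pd.Timestamp]:
    """Largest single-day temperature range as a fraction of the record
    range, with the day achieving it.

    A value above 0.4 means more than 40% of the record's total range was
    observed within one day.
    """
    daily = daily_summaries(series)
    total = float(series.data.max() - series.data.min())
    if total <= 0:
        raise ValueError("record temperature range is zero")
    frac = (daily["max"] - daily["min"]) / total
    i = int(frac.idxmax())
    return float(frac.iloc[i]), pd.Timestamp(daily["date"].iloc[i])
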