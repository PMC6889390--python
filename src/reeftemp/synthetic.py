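"""Synthetic shallow-reef temperature series.

The generator is statistical, not hydrodynamic. It reproduces the
features the downstream analysis keys on:

* a seasonal sinusoid (annual cycle of the running mean),
* diurnal (1 cpd) and lunar semidiurnal (default 1.9323 cpd, the M2
  tide) sinusoids whose amplitudes blend smoothly between summer and
  winter values over the year,
* episodic rapid cooling events — a Poisson process with season-
  dependent rate, exponentially distributed magnitudes and a smooth
  half-sine pulse of finite duration that only ever *lowers* the
  temperature below the deterministic baseline, and
* white Gaussian sensor noise.

Events and noise draw from independent sub-streams of one seeded RNG,
so toggling the noise level does not change which events occur.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SiteMeta, TemperatureSeries
from .extremes import ExtremeValueFit

__all__ = [
    "SyntheticConfig",
    "generate_series",
    "generate_paired_loggers",
    "sample_extremes",
]

#: Day-of-year at the center of the May–October summer season (Aug 1);
#: the summer/winter blending weight peaks here.
_SUMMER_CENTER_DOY = 213.0

_YEAR_DAYS = 365.25


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic logger record (all temperatures °C)."""

    start_date: dt.date = dt.date(2009, 7, 1)
    n_days: int = 365
    sample_interval_min: int = 20
    mean_temp: float = 23.0
    seasonal_amplitude: float = 5.5
    seasonal_phase: float = 227.0  # day-of-year of the seasonal maximum
    diurnal_amp_summer: float = 1.0
    diurnal_amp_winter: float = 0.25
    semidiurnal_amp_summer: float = 0.6
    semidiurnal_amp_winter: float = 0.15
    semidiurnal_freq: float = 1.9323  # cpd; lunar M2
    event_rate_summer: float = 0.3  # events/day
    event_rate_winter: float = 0.05
    event_mag_mean: float = 1.5  # mean cooling depth, °C
    event_duration_hr: float = 6.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = {
            "seasonal_amplitude": self.seasonal_amplitude,
            "diurnal_amp_summer": self.diurnal_amp_summer,
            "diurnal_amp_winter": self.diurnal_amp_winter,
            "semidiurnal_amp_summer": self.semidiurnal_amp_summer,
            "semidiurnal_amp_winter": self.semidiurnal_amp_winter,
            "event_rate_summer": self.event_rate_summer,
            "event_rate_winter": self.event_rate_winter,
            "event_mag_mean": self.event_mag_mean,
            "event_duration_hr": self.event_duration_hr,
            "noise_sd": self.noise_sd,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.sample_interval_min <= 0 or 1440 % self.sample_interval_min:
            raise ValueError(
                f"sample_interval_min must divide 1440, "
                f"got {self.sample_interval_min}"
            )
        if self.semidiurnal_freq <= 0:
            raise ValueError("semidiurnal_freq must be positive")


def _summer_weight(doy: np.ndarray) -> np.ndarray:
    """Smooth 0..1 weight, 1 at the center of summer, 0 mid-winter."""
    return 0.5 * (
        1.0 + np.cos(2 * np.pi * (doy - _SUMMER_CENTER_DOY) / _YEAR_DAYS)
    )


def _blend(w: np.ndarray, summer: float, winter: float) -> np.ndarray:
    return w * summer + (1.0 - w) * winter


def _deterministic_parts(config: SyntheticConfig):
    """Time grid, fractional day-of-year, and the sinusoidal baseline."""
    spd = 1440 // config.sample_interval_min
    n = config.n_days * spd
    index = pd.date_range(
        start=pd.Timestamp(config.start_date),
        periods=n,
        freq=f"{config.sample_interval_min}min",
    )
    hours = np.arange(n) * (config.sample_interval_min / 60.0)
    doy = index.dayofyear.to_numpy() + (
        index.hour.to_numpy() * 60 + index.minute.to_numpy()
    ) / 1440.0
    w = _summer_weight(doy)
    seasonal = config.mean_temp + config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.seasonal_phase) / _YEAR_DAYS
    )
    diurnal = _blend(
        w, config.diurnal_amp_summer, config.diurnal_amp_winter
    ) * np.cos(2 * np.pi * hours / 24.0)
    semidiurnal = _blend(
        w, config.semidiurnal_amp_summer, config.semidiurnal_amp_winter
    ) * np.cos(2 * np.pi * config.semidiurnal_freq * hours / 24.0)
    return index, hours, doy, seasonal + diurnal + semidiurnal


def _cooling_events(
    config: SyntheticConfig, hours: np.ndarray, doy: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Summed half-sine cooling pulses; non-negative, subtracted later.

    Event arrivals are Poisson per day with the rate blended between the
    seasonal values at each day's center.
    """
    cooling = np.zeros_like(hours)
    spd = 1440 // config.sample_interval_min
    dur = config.event_duration_hr
    for day in range(config.n_days):
        w_day = _summer_weight(np.array([doy[day * spd] + 0.5]))[0]
        rate = _blend(
            np.array([w_day]),
            config.event_rate_summer,
            config.event_rate_winter,
        )[0]
        n_events = rng.poisson(rate)
        for _ in range(n_events):
            t0 = (day + rng.uniform()) * 24.0  # start hour
            mag = rng.exponential(config.event_mag_mean)
            if dur <= 0:
                continue
            lo = np.searchsorted(hours, t0)
            hi = np.searchsorted(hours, t0 + dur)
            u = (hours[lo:hi] - t0) / dur
            cooling[lo:hi] += mag * np.sin(np.pi * u)
    return cooling


def _check_length(config: SyntheticConfig) -> None:
    # shortest record that still supports a 29-day centered window with a
    # fully covered day on each side of center
    if config.n_days < 58:
        raise ValueError(
            f"n_days must be >= 58 to support the 29-day centered "
            f"running mean, got {config.n_days}"
        )


_DEFAULT_META = SiteMeta(site_id=1, name="synthetic", lat=28.0, lon=112.0)


def generate_series(
    config: SyntheticConfig, meta: SiteMeta = _DEFAULT_META
) -> TemperatureSeries:
    """Generate one logger record. Identical config + seed → identical
    output, bit for bit."""
    _check_length(config)
    index, hours, doy, baseline = _deterministic_parts(config)
    ev_rng, noise_rng = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence([config.seed]).spawn(2)
    ]
    cooling = _cooling_events(config, hours, doy, ev_rng)
    noise = noise_rng.standard_normal(len(hours)) * config.noise_sd
    temps = baseline - cooling + noise
    return TemperatureSeries(meta=meta, data=pd.Series(temps, index=index))


def generate_paired_loggers(
    config: SyntheticConfig, meta: SiteMeta = _DEFAULT_META
) -> tuple[TemperatureSeries, TemperatureSeries]:
    """Two redundant loggers: one latent signal, independent noise.

    The first logger reproduces :func:`generate_series` for the same
    config exactly (it shares the event and noise sub-streams).
    """
    _check_length(config)
    index, hours, doy, baseline = _deterministic_parts(config)
    ev_rng, noise_a, noise_b = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence([config.seed]).spawn(3)
    ]
    latent = baseline - _cooling_events(config, hours, doy, ev_rng)
    out = []
    for noise_rng in (noise_a, noise_b):
        noise = noise_rng.standard_normal(len(hours)) * config.noise_sd
        out.append(
            TemperatureSeries(
                meta=meta, data=pd.Series(latent + noise, index=index)
            )
        )
    return out[0], out[1]


def sample_extremes(
    fit: ExtremeValueFit, n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` i.i.d. daily-extreme anomalies from a fitted asymptote.

    Inverse-CDF sampling: solve P(x) = u for u ~ Uniform(0, 1). Draws
    respect the support bound α/β when β ≠ 0.
    """
    fit.validate()
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    a, b, e = fit.alpha, fit.beta, fit.epsilon
    g = -np.log(u)  # standard exponential
    if abs(b) < 1e-8:
        return e - a * np.log(g)
    return (a - (a - b * e) * g**b) / b
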