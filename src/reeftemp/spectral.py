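"""Welch power spectral density and band-integrated rms variability.

Spectra are averaged over 14-day (1008-sample at 20-min) Hamming-
windowed sections with 50% overlap, each linearly detrended so the
strong seasonal trend does not leak into low frequencies. The PSD is
one-sided, in °C² per cycle-per-hour, so integrating it over a band and
taking the square root gives the band rms amplitude in °C directly.

The two bands of interest bracket the prominent spectral peaks of
shallow-reef records: diurnal (periods 20–33 h, solar and wind forcing)
and semidiurnal (periods 11–14 h, the lunar M2 tide and internal waves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import TemperatureSeries

__all__ = [
    "SpectralParams",
    "PowerSpectrum",
    "BandDefinition",
    "BandRMS",
    "DIURNAL_BAND",
    "SEMIDIURNAL_BAND",
    "welch_psd",
    "band_rms",
    "band_rms_by_site",
]


@dataclass(frozen=True)
class SpectralParams:
    """Welch estimator settings.

    ``min_segment_coverage`` is the valid-sample fraction a segment needs
    to be admitted; admitted segments have their remaining gaps filled
    with the segment mean before detrending and windowing.
    """

    segment_len_samples: int = 1008  # 14 days at 20-min sampling
    window: str = "hamming"
    overlap_fraction: float = 0.5
    detrend: str = "linear"  # "linear" | "constant" | "none"
    min_segment_coverage: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.segment_len_samples < 8:
            raise ValueError("segment_len_samples too small")


@dataclass
class PowerSpectrum:
    """One-sided Welch PSD: frequencies in cph, density in °C²/cph."""

    frequencies: np.ndarray
    psd: np.ndarray
    params: SpectralParams
    n_segments: int


@dataclass(frozen=True)
class BandDefinition:
    f_lo: float  # cph
    f_hi: float  # cph
    name: str

    def __post_init__(self) -> None:
        if not 0.0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band [{self.f_lo}, {self.f_hi}]")


#: Periods between 20 and 33 hours.
DIURNAL_BAND = BandDefinition(1.0 / 33.0, 1.0 / 20.0, "diurnal")
#: Periods between 11 and 14 hours (lunar semidiurnal).
SEMIDIURNAL_BAND = BandDefinition(1.0 / 14.0, 1.0 / 11.0, "semidiurnal")


@dataclass(frozen=True)
class BandRMS:
    band: BandDefinition
    rms: float


def welch_psd(
    series: TemperatureSeries, params: SpectralParams | None = None
) -> PowerSpectrum:
    """Welch PSD averaged over admissible overlapping segments.

    Segments with more than ``1 − min_segment_coverage`` missing samples
    are dropped (so the segment count stays honest across gaps and
    season masks); gaps inside admitted segments are filled with the
    segment mean, which adds no power at nonzero frequency.
    """
    params = params or SpectralParams()
    nper = params.segment_len_samples
    x = series.temps
    if len(x) < nper:
        raise ValueError(
            f"series length {len(x)} shorter than one segment ({nper})"
        )
    fs = 60.0 / series.interval_minutes  # samples per hour
    step = max(1, int(round(nper * (1.0 - params.overlap_fraction))))
    win = signal.get_window(params.window, nper)
    norm = fs * np.sum(win**2)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)

    acc = np.zeros(len(freqs))
    n_segments = 0
    for start in range(0, len(x) - nper + 1, step):
        seg = x[start : start + nper]
        valid = np.isfinite(seg)
        if valid.mean() < params.min_segment_coverage:
            continue
        seg = np.where(valid, seg, seg[valid].mean())
        if params.detrend == "linear":
            seg = signal.detrend(seg, type="linear")
        elif params.detrend == "constant":
            seg = seg - seg.mean()
        spec = np.abs(np.fft.rfft(seg * win)) ** 2 * (2.0 / norm)
        spec[0] /= 2.0
        if nper % 2 == 0:
            spec[-1] /= 2.0
        acc += spec
        n_segments += 1
    if n_segments == 0:
        raise ValueError("no segment met the coverage requirement")
    return PowerSpectrum(
        frequencies=freqs, psd=acc / n_segments, params=params,
        n_segments=n_segments,
    )


def band_rms(spectrum: PowerSpectrum, band: BandDefinition) -> BandRMS:
    """rms amplitude = sqrt of the PSD integral over [f_lo, f_hi].

    Trapezoidal integration on the discrete frequency grid, with the
    band edges included by linear interpolation.
    """
    f, p = spectrum.frequencies, spectrum.psd
    if band.f_lo < f[0] or band.f_hi > f[-1]:
        raise ValueError(
            f"band [{band.f_lo:.4g}, {band.f_hi:.4g}] outside the "
            f"spectrum's range [{f[0]:.4g}, {f[-1]:.4g}]"
        )
    inside = (f > band.f_lo) & (f < band.f_hi)
    grid = np.concatenate(([band.f_lo], f[inside], [band.f_hi]))
    vals = np.concatenate(
        (
            [np.interp(band.f_lo, f, p)],
            p[inside],
            [np.interp(band.f_hi, f, p)],
        )
    )
    power = float(np.trapezoid(vals, grid))
    return BandRMS(band=band, rms=float(np.sqrt(max(power, 0.0))))


def band_rms_by_site(
    series_list: list[TemperatureSeries],
    bands: tuple[BandDefinition, ...] = (DIURNAL_BAND, SEMIDIURNAL_BAND),
    params: SpectralParams | None = None,
) -> pd.DataFrame:
    """Long-format (site, band, rms) table across sites.

    Sites whose record cannot support the estimator (all missing, or
    shorter than one segment) are omitted with a warning.
    """
    if not series_list:
        raise ValueError("no sites supplied")
    rows = []
    for series in series_list:
        try:
            spectrum = welch_psd(series, params)
        except ValueError as exc:
            warnings.warn(
                f"site {series.meta.site_id} ({series.meta.name}) "
                f"skipped: {exc}",
                stacklevel=2,
            )
            continue
        for band in bands:
            rows.append(
                {
                    "site_id": series.meta.site_id,
                    "site_name": series.meta.name,
                    "band": band.name,
                    "rms_c": band_rms(spectrum, band).rms,
                }
            )
    return pd.DataFrame(rows, columns=["site_id", "site_name", "band", "rms_c"])
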