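"""Cold-anomaly statistics of extremes: daily minimum cooling anomalies,
asymptotic CDF fitting, and median return times.

The quantity of interest is the daily minimum *cooling anomaly*

    x_i = (29-day centered running mean on day i) − (day i's minimum),

so larger x means deeper cooling below seasonal conditions. Under
independence and stationarity, the distribution of the daily extremes
approaches the asymptotic form

    P(x) = exp(−[(α − βx)/(α − βε)]^(1/β)),

with P = 1 for x ≥ α/β when β > 0 and P = 0 for x ≤ α/β when β < 0.
Here ε is the mode (P(ε) = e⁻¹ identically), α sets the rate at which
P grows with ln(time), and α/β (β > 0) is the largest achievable
anomaly. This is a generalized-extreme-value family: in the usual
(shape ξ, loc μ, scale σ) parameterisation it is ξ = −β, μ = ε,
σ = α − βε, and β → 0 gives the Gumbel form
P(x) = exp(−exp(−(x − ε)/α)).

The predicted median return time of an anomaly of size x, in units of
the daily sampling interval, is τ(x) = 1/(1 − P(x)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import SmoothedSeries, TemperatureSeries
from .preprocess import SUMMER_MONTHS

__all__ = [
    "AnomalySeries",
    "RankedExtremes",
    "ExtremeValueFit",
    "ReturnTimeEstimate",
    "daily_min_anomalies",
    "decorrelate",
    "rank_extremes",
    "eval_probability",
    "return_time",
    "fit_extreme_value",
    "max_expected_anomaly",
    "return_time_table",
]

#: |β| below which the Gumbel-limit branch is used (avoids 1/β overflow).
GUMBEL_SWITCH = 1e-8

#: Return times longer than this many days are flagged censored
#: (rendered "*" in tables).
CENSOR_DAYS = 1000.0

#: τ at the mode: 1/(1 − e⁻¹).
TAU_AT_MODE = 1.0 / (1.0 - np.exp(-1.0))


@dataclass
class AnomalySeries:
    """Daily minimum cooling anomalies (positive = cooling below the
    running mean), with a season label per day."""

    dates: pd.DatetimeIndex
    anomaly: np.ndarray
    season: np.ndarray  # "summer" | "winter" per date

    def __post_init__(self) -> None:
        if not (len(self.dates) == len(self.anomaly) == len(self.season)):
            raise ValueError("misaligned anomaly series")
        if not np.all(np.isfinite(self.anomaly)):
            raise ValueError("anomalies must be finite")

    def __len__(self) -> int:
        return len(self.anomaly)

    def select_season(self, season: str) -> "AnomalySeries":
        keep = self.season == season
        return AnomalySeries(
            self.dates[keep], self.anomaly[keep], self.season[keep]
        )


@dataclass
class RankedExtremes:
    """Ascending extremes with Weibull plotting positions i/(n+1)."""

    values: np.ndarray
    plotting_positions: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.values) < 0):
            raise ValueError("values must be sorted ascending")
        p = self.plotting_positions
        if np.any(p <= 0) or np.any(p >= 1) or np.any(np.diff(p) <= 0):
            raise ValueError("plotting positions must be increasing in (0,1)")


@dataclass
class ExtremeValueFit:
    """The (α, β, ε) triple of the asymptotic CDF for one site × season."""

    alpha: float
    beta: float
    epsilon: float
    season: str | None = None
    site_id: int | None = None
    n_points_fit: int | None = None
    residual_norm: float | None = None

    def validate(self) -> None:
        if not np.isfinite([self.alpha, self.beta, self.epsilon]).all():
            raise ValueError("fit parameters must be finite")
        if self.alpha - self.beta * self.epsilon <= 0:
            raise ValueError(
                f"invalid fit: alpha - beta*epsilon = "
                f"{self.alpha - self.beta * self.epsilon:.4g} <= 0"
            )

    @property
    def bound(self) -> float:
        """Support bound α/β (+inf for the Gumbel case β = 0)."""
        if abs(self.beta) < GUMBEL_SWITCH:
            return np.inf
        return self.alpha / self.beta


@dataclass(frozen=True)
class ReturnTimeEstimate:
    anomaly: float
    tau_days: float
    censored: bool


# ---------------------------------------------------------------------
# Anomaly extraction


def daily_min_anomalies(
    series: TemperatureSeries, smoothed: SmoothedSeries
) -> AnomalySeries:
    """One cooling anomaly per day: running mean at the day's center
    minus the day's minimum temperature.

    The running-mean reference for a day is its value at the sample
    nearest local noon. Days without a valid running mean there, or
    without any valid temperature sample, are skipped.
    """
    if len(smoothed.timestamps) != len(series.timestamps) or not (
        smoothed.timestamps == series.timestamps
    ).all():
        raise ValueError("smoothed series not aligned with raw series")
    frame = pd.DataFrame(
        {"temp": series.temps, "rm": smoothed.running_mean},
        index=series.timestamps,
    )
    dates, anoms = [], []
    for day, group in frame.groupby(frame.index.normalize()):
        tmin = group["temp"].min()
        if not np.isfinite(tmin):
            continue
        center = day + pd.Timedelta(hours=12)
        pos = group.index.get_indexer([center], method="nearest")[0]
        rm = group["rm"].iloc[pos]
        if not np.isfinite(rm):
            continue
        dates.append(day)
        anoms.append(float(rm - tmin))
    if not dates:
        raise ValueError("no days with a valid running mean and samples")
    idx = pd.DatetimeIndex(dates)
    season = np.where(
        idx.month.isin(sorted(SUMMER_MONTHS)), "summer", "winter"
    )
    return AnomalySeries(idx, np.asarray(anoms), season)


def decorrelate(
    anoms: AnomalySeries, stride: int = 4, phase: int = 0
) -> AnomalySeries:
    """Keep every ``stride``-th day to suppress serial autocorrelation.

    The default stride of 4 days exceeds the decorrelation time of the
    daily anomaly series; ``phase`` selects which of the stride offsets
    is retained (0 = first valid day).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sl = slice(phase, None, stride)
    return AnomalySeries(
        anoms.dates[sl], anoms.anomaly[sl], anoms.season[sl]
    )


def rank_extremes(anoms: AnomalySeries | np.ndarray) -> RankedExtremes:
    """Rank extremes ascending and assign i/(n+1) plotting positions."""
    values = (
        anoms.anomaly if isinstance(anoms, AnomalySeries) else np.asarray(anoms)
    ).astype(float)
    n = len(values)
    if n < 8:
        raise ValueError(
            f"need at least 8 extremes for a 3-parameter fit, got n={n}"
        )
    order = np.argsort(values, kind="stable")  # ties keep occurrence order
    positions = np.arange(1, n + 1) / (n + 1)
    return RankedExtremes(values[order], positions)


# ---------------------------------------------------------------------
# The asymptotic CDF and return times


def eval_probability(fit: ExtremeValueFit, x) -> np.ndarray | float:
    """Non-exceedance probability P(x) under the fitted asymptote.

    Uses the Gumbel-limit branch for |β| < 1e−8 and a log1p formulation
    otherwise, which stays accurate through β → 0.
    """
    fit.validate()
    a, b, e = fit.alpha, fit.beta, fit.epsilon
    scalar_in = np.ndim(x) == 0
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if abs(b) < GUMBEL_SWITCH:
        p = np.exp(-np.exp(-(x_arr - e) / a))
    else:
        scale = a - b * e
        base = 1.0 - b * (x_arr - e) / scale  # = (a - b x)/(a - b e)
        p = np.empty_like(x_arr)
        inside = base > 0
        with np.errstate(over="ignore"):
            p[inside] = np.exp(
                -np.exp(np.log1p(-b * (x_arr[inside] - e) / scale) / b)
            )
        # outside the support: P = 1 beyond the upper bound (β > 0),
        # P = 0 below the lower bound (β < 0)
        p[~inside] = 1.0 if b > 0 else 0.0
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar_in else p


def return_time(
    fit: ExtremeValueFit,
    x: float,
    record_length_days: float | None = None,
    censor_days: float = CENSOR_DAYS,
) -> ReturnTimeEstimate:
    """Predicted median return time τ(x) = 1/(1 − P(x)) in days.

    The estimate is flagged censored when it exceeds ``censor_days``
    (default 1000, the tabular "*" convention) or the observed record
    length, beyond which the extrapolation should not be trusted.
    """
    p = eval_probability(fit, float(x))
    tau = np.inf if p >= 1.0 else 1.0 / (1.0 - p)
    censored = tau > censor_days or (
        record_length_days is not None and tau > record_length_days
    )
    return ReturnTimeEstimate(anomaly=float(x), tau_days=tau, censored=censored)


def max_expected_anomaly(fit: ExtremeValueFit, period_days: float) -> float:
    """Largest anomaly expected once per ``period_days`` — the x solving
    τ(x) = period_days, by closed-form inversion."""
    fit.validate()
    if period_days <= TAU_AT_MODE:
        raise ValueError(
            f"period must exceed tau at the mode ({TAU_AT_MODE:.4f} days)"
        )
    a, b, e = fit.alpha, fit.beta, fit.epsilon
    q = -np.log1p(-1.0 / period_days)  # −ln(1 − 1/T) > 0
    if abs(b) < GUMBEL_SWITCH:
        return float(e - a * np.log(q))
    x = (a - (a - b * e) * q**b) / b
    if b > 0 and x > a / b:
        raise ValueError(
            f"period {period_days} exceeds the attainable range; "
            f"anomalies are bounded by alpha/beta = {a / b:.4g}"
        )
    return float(x)


# ---------------------------------------------------------------------
# Fitting


def _cdf_ls_fit(ranked: RankedExtremes) -> tuple[np.ndarray, float]:
    x, p = ranked.values, ranked.plotting_positions
    e0 = float(np.median(x))
    sd = float(np.std(x, ddof=1))
    a0 = sd * np.sqrt(6.0) / np.pi  # Gumbel moment estimate
    theta0 = np.array([a0, 0.0, e0])

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, e = theta
        scale = a - b * e  # must stay positive (also covers a > 0 at b ~ 0)
        if scale <= 1e-9:
            return np.full(len(x) + 1, 1e3)
        if abs(b) < GUMBEL_SWITCH:
            model = np.exp(-np.exp(-(x - e) / a))
        else:
            base = 1.0 - b * (x - e) / scale
            model = np.where(
                base > 0,
                np.exp(-np.where(base > 0, base, 1.0) ** (1.0 / b)),
                1.0 if b > 0 else 0.0,
            )
        # the support bound alpha/beta must cover the observed range,
        # with a small margin so no datum sits exactly on the bound
        margin = 0.01 * (x[-1] - x[0])
        if b > 0:
            pen = max(0.0, b * (x[-1] + margin) - a)
        elif b < 0:
            pen = max(0.0, b * (x[0] - margin) - a)
        else:
            pen = 0.0
        return np.append(model - p, 100.0 * pen)

    sol = optimize.least_squares(
        residuals,
        theta0,
        bounds=([-np.inf, -5.0, -np.inf], [np.inf, 5.0, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=5000,
    )
    if not sol.success:
        raise RuntimeError(
            f"CDF least-squares fit did not converge: {sol.message}; "
            f"best iterate alpha={sol.x[0]:.4g}, beta={sol.x[1]:.4g}, "
            f"epsilon={sol.x[2]:.4g}, cost={sol.cost:.4g}"
        )
    return sol.x, float(np.linalg.norm(sol.fun[:-1]))


def _mle_fit(values: np.ndarray) -> tuple[np.ndarray, float]:
    # scipy's genextreme shape c equals β here; loc = ε, scale = α − βε
    c, loc, scale = stats.genextreme.fit(values)
    theta = np.array([scale + c * loc, c, loc])
    nll = -np.sum(stats.genextreme.logpdf(values, c, loc, scale))
    return theta, float(nll)


def fit_extreme_value(
    ranked: RankedExtremes,
    method: str = "cdf-ls",
    season: str | None = None,
    site_id: int | None = None,
) -> ExtremeValueFit:
    """Fit (α, β, ε) to ranked daily extremes.

    ``method="cdf-ls"`` (default) minimizes the squared deviation between
    the asymptotic CDF and the empirical plotting positions — the direct
    realization of fitting a continuous probability function to the
    ranked extremes' cumulative distribution. ``method="mle"`` is the
    standard GEV maximum-likelihood fit on the values themselves.
    """
    values = ranked.values
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all extremes are equal")
    if method == "cdf-ls":
        theta, resid = _cdf_ls_fit(ranked)
    elif method == "mle":
        theta, resid = _mle_fit(values)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    fit = ExtremeValueFit(
        alpha=float(theta[0]),
        beta=float(theta[1]),
        epsilon=float(theta[2]),
        season=season,
        site_id=site_id,
        n_points_fit=len(values),
        residual_norm=resid,
    )
    fit.validate()
    if fit.beta > GUMBEL_SWITCH and fit.bound < values[-1] - 1e-6:
        raise RuntimeError(
            f"fit support bound alpha/beta = {fit.bound:.4g} does not "
            f"cover the largest observed extreme {values[-1]:.4g}"
        )
    if fit.beta < -GUMBEL_SWITCH and fit.bound > values[0] + 1e-6:
        raise RuntimeError(
            f"fit support bound alpha/beta = {fit.bound:.4g} does not "
            f"cover the smallest observed extreme {values[0]:.4g}"
        )
    return fit


# ---------------------------------------------------------------------
# Tables


def return_time_table(
    fits: list[ExtremeValueFit],
    anomalies: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0),
    censor_days: float = CENSOR_DAYS,
    record_length_days: float | None = None,
    site_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-site predicted return times at the requested anomaly levels.

    Return times are rounded to the nearest whole day; censored entries
    (τ > ``censor_days`` or beyond the record) are rendered "*".
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for fit in fits:
        row: dict[str, object] = {"site_id": fit.site_id}
        if site_names is not None:
            row["site_name"] = site_names.get(fit.site_id, "")
        for x in anomalies:
            est = return_time(
                fit, x, record_length_days=record_length_days,
                censor_days=censor_days,
            )
            label = f"delta_{x:g}"
            row[label] = "*" if est.censored else str(int(round(est.tau_days)))
        row["alpha"] = fit.alpha
        row["beta"] = fit.beta
        row["epsilon"] = fit.epsilon
        row["season"] = fit.season
        rows.append(row)
    return pd.DataFrame(rows)
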