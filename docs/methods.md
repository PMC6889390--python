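# Methods

## Data model and preprocessing

A site's record is a strictly regular grid of naive local timestamps
(default 20-min interval, 72 samples/day) with explicit `NaN` gaps —
missing samples are never interpolated, because interpolation across a
cooling event would fabricate or erase exactly the extremes this
analysis measures. Day boundaries fall at local midnight of the naive
timestamps; loggers are assumed to record local deployment time.

Redundant paired loggers are combined as the element-wise mean at each
shared time point; where only one logger has a value, that value is used
unchanged, and the sample stays missing only where both are missing.
This matches standard practice for duplicate in-situ sensors and makes
merging symmetric.

The low-frequency reference is a 29-day centered running mean on the raw
grid (window of `29 × 72 + 1` samples, both half-window ends included).
Each window records its *coverage* — the fraction of its nominal length
occupied by valid samples — and the running mean is set missing wherever
coverage falls below 0.9. This trims roughly 14.5 days at each record
end and around large gaps; a looser threshold would let trend bias leak
into the anomalies at the edges, a stricter one discards data around
every small gap. Whole-record and daily summary statistics use the
sample (n−1) standard deviation, the usual convention for summary
tables.

Seasons are fixed calendar halves: summer May–October, winter
November–April. `seasonal_split` keeps the full regular grid and masks
the other season's samples to missing rather than producing an irregular
row subset; the two halves partition the valid samples exactly, and
segment-based spectral estimation then drops mixed segments naturally.

## Spectral estimation

PSDs are estimated by Welch's method: 14-day segments (1008 samples at
20 min) with 50% overlap, Hamming window, one-sided density
normalization in °C² per cycle-per-hour (Nyquist 1.5 cph). Each segment
is linearly detrended before windowing; without this the seasonal cycle
leaks broadband power into the lowest frequencies and inflates band
integrals. A segment is admitted only if at least 95% of its samples
are valid, and the remaining gaps are filled with the segment mean
(which adds no power at nonzero frequency); this keeps the averaged
segment count honest rather than silently averaging over fabricated
data. On gap-free input the estimator agrees with
`scipy.signal.welch` to rounding error (this is checked in the tests);
the hand-rolled segment loop exists only to carry the gap policy.

Band rms is the square root of the trapezoidal integral of the PSD over
a band, with the band edges included by linear interpolation on the
discrete frequency grid. The two default bands are diurnal
(1/33–1/20 cph, periods 20–33 h) and semidiurnal (1/14–1/11 cph, periods
11–14 h, bracketing the lunar M2 frequency of ≈1.932 cpd); band widths
are held fixed across sites so integrated magnitudes are comparable.
With this normalization a pure sinusoid of amplitude A whose frequency
lies inside a band contributes A/√2 to that band's rms.

## Extreme-value model

The daily minimum cooling anomaly is
`x = (running mean) − (daily minimum)`, positive for cooling. The
running-mean reference for a day is its value at the sample nearest
local noon — the center of that day's window; using a per-day average of
the running mean instead changes anomalies by well under the logger
resolution. Days without a valid running mean there are skipped.

The anomaly series is subsampled to every 4th day before fitting, since
daily anomalies are serially correlated over a few days; the subsample
phase defaults to the first valid day and is configurable, so
sensitivity across the four phases can be reported. Seasonal fits are
computed separately for summer and winter because the variance is
strongly non-stationary across seasons.

Extremes are ranked ascending with Weibull plotting positions i/(n+1)
(unbiased non-exceedance probabilities), and the asymptotic CDF

    P(x) = exp(−[(α − βx)/(α − βε)]^(1/β))

is fit to the plotting positions. The family is a generalized
extreme-value distribution in disguise: shape ξ = −β, location μ = ε,
scale σ = α − βε > 0, which is the validity requirement enforced
throughout (α itself may be any sign for strongly heavy-tailed fits).
Two fitting routes are provided:

* `cdf-ls` (default): nonlinear least squares of the CDF against the
  plotting positions (`scipy.optimize.least_squares`, trust-region
  reflective), initialized at the Gumbel moment estimates
  (ε₀ = median, α₀ = s·√6/π, β₀ = 0). The support bound α/β must cover
  the observed data range — a fit that assigns probability 0 or 1 to an
  observed extreme is rejected — enforced by a smooth penalty with a 1%
  margin of the data range and verified after convergence.
* `mle`: the standard GEV maximum-likelihood fit on the values
  (`scipy.stats.genextreme`), mapped back to (α, β, ε).

The CDF route is the default because it realizes the ranked-extremes
procedure directly; the MLE route is the statistically standard
alternative and doubles as an independent cross-check in the tests.

Numerical choices: the β = 0 (Gumbel) branch is taken for |β| < 1e−8 to
avoid 1/β overflow, and the general branch is evaluated through
`log1p`, so the two branches agree to a relative difference below 1e−4
at |β| = 1e−6. `P(ε) = 1/e` holds identically in both branches.
Degenerate inputs (fewer than 8 extremes, or all extremes equal) are
rejected rather than fit.

Return times are `τ(x) = 1/(1 − P(x))` in days (the subsampling interval
cancels: P is per-interval, τ counts intervals of the fitted daily
extremes). Tabular output rounds to whole days; estimates above 1000
days, or beyond the observed record length when it is supplied, are
flagged censored and rendered `*` — extrapolations past the record
should be viewed circumspectly or disregarded. The inverse problem
(largest anomaly expected once per period) is solved in closed form,
`x = [α − (α − βε)(−ln(1 − 1/T))^β]/β`, with the Gumbel closed form at
β = 0; for β > 0 the result approaches the ceiling α/β as the period
grows.

Warm-anomaly return times are deliberately out of scope: the variability
this pipeline targets is dominated by rapid cooling below the running
mean, and a useful warm-extreme analysis would need multi-year records
capturing inter-annual forcing.

## Synthetic generator

The generator is statistical, not hydrodynamic — no tide model, internal
wave dynamics or heat budget. It emulates the features the analysis
keys on:

* seasonal sinusoid: mean 23 °C, amplitude 5.5 °C, maximum at day-of-year
  227 (mid-August), giving a running-mean span of ≈17.5–28.5 °C; with
  events and noise the record spans roughly 15–31 °C, the scale of
  subtropical shallow-reef records;
* diurnal (1 cpd) and semidiurnal (1.9323 cpd, M2) sinusoids whose
  amplitudes blend between summer values (1.0 and 0.6 °C) and winter
  values (0.25 and 0.15 °C) by a smooth sinusoidal weight over
  day-of-year peaking at the center of the May–October summer — the
  simplest periodic blend without season-boundary discontinuities;
* cooling events: a Poisson process (0.3/day in summer, 0.05/day in
  winter, blended the same way) of half-sine pulses, default 6 h wide,
  with exponentially distributed depths (mean 1.5 °C). Pulses only ever
  subtract from the deterministic baseline, so warm-side daily anomalies
  of an event-only series stay near zero. No published event rates or
  magnitudes exist for these sites; the defaults were chosen once to
  give summer-dominated variance, diurnal > semidiurnal band rms, and
  occasional 2–5 °C daily cooling anomalies, and are not tuned further;
* Gaussian sensor noise (sd 0.1 °C, roughly logger accuracy).

Events and noise draw from sub-streams spawned from one seed, so
toggling noise does not change which events occur, identical configs are
bit-identical, and the first logger of a simulated pair reproduces the
single-logger output exactly.

What the generator does *not* emulate: correlated event clustering
(real upwelling events span consecutive days), asymmetric event shapes,
tidal spring–neap modulation, sensor drift, and data gaps. Passing
tests on synthetic data therefore demonstrate that the pipeline
computes its statistics correctly on records with the assumed structure,
not that the statistical assumptions (independence of 4-day-subsampled
extremes, within-season stationarity) hold for any particular field
record.

`sample_extremes` draws i.i.d. daily extremes by inverse-CDF sampling of
the fitted family, used for parameter-recovery and return-time-oracle
tests. For i.i.d. daily extremes the gaps between successive
exceedances of a level x are geometric with mean 1/(1 − P(x)), so the
mean inter-exceedance gap is the empirical estimator checked against
τ(x); the *typical* (median) gap of a geometric distribution is shorter
by a factor ≈ ln 2, which is worth remembering when reading τ as "the
expected wait".

## Pipeline and reproducibility

One YAML config drives simulate → summarize → spectra → extremes and
writes `table1.csv`, `daily_summaries.csv`, `psd_<site>.csv`,
`band_rms.csv`, `table2.csv` and a `manifest.json` (config hash, seed,
version, per-stage counts; the hash excludes input/output paths).
Per-site generator seeds derive deterministically from (global seed,
site id), so a rerun with the same config is byte-identical. A failing
site aborts with the stage name and site id, or is skipped with a
warning when `skip_failed_sites` is set; other sites' outputs are
unaffected.

Default problem sizes in the tests and examples (90–365 synthetic days,
2–3 sites, 500-draw fit replicates) are desk-scale choices: they are
large enough for every statistical tolerance asserted while keeping the
full suite in the seconds-to-minutes range.

## Known limitations

* The CDF least-squares fit weights the body and tail of the ranked
  sample equally; with few exceedances the fitted tail can disagree
  noticeably with empirical exceedance frequencies. The MLE route and
  the censoring rules are the guard rails.
* Mixture-like anomaly distributions (a sinusoidal baseline dip plus
  episodic events, as the generator produces) are not GEV; fits on such
  data describe the empirical CDF, and their extrapolations beyond the
  observed range inherit the model error.
* The running-mean coverage rule discards ~2 weeks at each record end,
  so single-season records shorter than about two months leave too few
  subsampled extremes to fit.
* Band rms compares variability *within* the fixed bands only; energy
  between the bands (e.g. inertial peaks) is not attributed.
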