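# reeftemp

Analysis of fixed-interval (20-min) temperature logger records from
shallow rocky reefs: how variable is the thermal environment at each
site, at which frequencies is the variability concentrated, and how
often should benthic organisms expect cold-water anomalies of a given
magnitude?

The package is aimed at coastal ecologists and physical oceanographers
working with multi-site logger deployments (e.g. along the western Gulf
of California, where within-day cooling events of 2–5 °C driven by wind
forcing, upwelling and internal waves are common in summer). It
provides four stages, usable as a library or from a CLI, plus a
synthetic-data generator so the whole pipeline runs and is testable
without field data:

1. **preprocess** — logger CSV ingestion, merging of redundant paired
   loggers (mean at each shared time point, single-logger fallback),
   29-day centered running means, daily and whole-record summary
   statistics, May–October / November–April seasonal splits.
2. **spectral** — Welch power spectral density over 14-day
   (1008-sample) Hamming-windowed sections with 50% overlap, and rms
   variability integrated over the diurnal (periods 20–33 h) and
   semidiurnal (11–14 h) frequency bands.
3. **extremes** — the statistic-of-extremes model for daily minimum
   cooling anomalies and their predicted median return times.
4. **synthetic** — seasonal + diurnal + semidiurnal sinusoids,
   Poisson-arriving cooling events, and Gaussian sensor noise, with
   bit-reproducible seeding.

## The model

For each day the *cooling anomaly* is
`x_i = (29-day running mean) − (daily minimum temperature)`, so larger
x means deeper cooling below seasonal conditions. Daily extremes are
subsampled every 4th day (to suppress serial correlation), ranked, and
assigned plotting positions i/(n+1). The non-exceedance probability
P(x) = Prob(x_i ≤ x) is fit with the asymptotic extreme-value form

    P(x) = exp(−[(α − βx)/(α − βε)]^(1/β)),

with P = 1 for x ≥ α/β when β > 0 and P = 0 for x ≤ α/β when β < 0;
the β → 0 limit is the Gumbel form `exp(−exp(−(x − ε)/α))`. ε is the
mode (P(ε) = 1/e identically), α the rate of increase of P with
ln(time), and α/β (for β > 0) the largest achievable anomaly. The
predicted median return time in days is

    τ(x) = 1 / (1 − P(x)),

and its closed-form inverse gives the largest anomaly expected once in
any chosen period. Estimates longer than 1000 days (or the record
length) are flagged censored and rendered `*` in tables.

## Worked example

```python
import reeftemp as rt

# one year of synthetic 20-min logger data for a northern-gulf-style site
config = rt.SyntheticConfig(n_days=365, seed=11)
series = rt.generate_series(config, meta=rt.SiteMeta(1, "North Reef", 29.0, 113.5))

summary = rt.site_summary(series)
print(f"record: mean {summary.mean:.1f} C, range {summary.range:.1f} C")

spectrum = rt.welch_psd(series)
for band in (rt.DIURNAL_BAND, rt.SEMIDIURNAL_BAND):
    print(f"{band.name} band rms: {rt.band_rms(spectrum, band).rms:.3f} C")

smoothed = rt.running_mean(series)                      # 29-day centered mean
anoms = rt.daily_min_anomalies(series, smoothed)        # daily cooling anomalies
summer = rt.decorrelate(anoms.select_season("summer"))  # every 4th day
fit = rt.fit_extreme_value(rt.rank_extremes(summer), season="summer", site_id=1)
print(f"fit: alpha={fit.alpha:.3f} beta={fit.beta:.3f} epsilon={fit.epsilon:.3f}")
for x in (2.0, 3.0):
    est = rt.return_time(fit, x)
    label = "*" if est.censored else f"{est.tau_days:.0f} days"
    print(f"return time of a {x:.0f} C cooling anomaly: {label}")
```

prints

```
record: mean 23.0 C, range 15.3 C
diurnal band rms: 0.495 C
semidiurnal band rms: 0.315 C
fit: alpha=0.411 beta=0.095 epsilon=1.086
return time of a 2 C cooling anomaly: 34 days
return time of a 3 C cooling anomaly: *
```

The record's whole range (15.3 °C) and the dominance of the diurnal
over the semidiurnal band are features of this site's configuration.
The fitted mode ε ≈ 1.1 °C says a typical day's minimum sits about a
degree below the running mean; a 2 °C cooling anomaly recurs roughly
monthly in summer, while the 3 °C estimate exceeds the censoring
threshold (`*`) — under this fit it should not be extrapolated.

The same stages run from the shell:

```
reeftemp simulate --config site.yaml --out data/ --paired
reeftemp summarize --in data/ --out results/
reeftemp spectra   --in data/ --out results/
reeftemp extremes  --in data/ --out results/ --season summer
reeftemp run --config pipeline.yaml     # all stages + manifest
```

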