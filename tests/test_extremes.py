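"""Cooling anomalies, the asymptotic CDF, fitting, and return times."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import reeftemp as rt
from reeftemp.extremes import TAU_AT_MODE

# published-style coefficient triples used as worked examples
SITE16 = rt.ExtremeValueFit(alpha=1.02, beta=0.19, epsilon=0.367, site_id=16)
SITE14 = rt.ExtremeValueFit(alpha=0.942, beta=-0.015, epsilon=0.463, site_id=14)
SITE10 = rt.ExtremeValueFit(alpha=0.61, beta=-0.216, epsilon=0.676, site_id=10)


def _random_valid_fits(n, seed):
    rng = np.random.default_rng(seed)
    fits = []
    while len(fits) < n:
        a = rng.uniform(0.3, 2.0)
        b = rng.uniform(-0.45, 0.45)
        e = rng.uniform(-0.5, 1.5)
        if a - b * e > 0.05:
            fits.append(rt.ExtremeValueFit(a, b, e))
    return fits


class TestDailyMinAnomalies:
    def test_constant_series_gives_zero(self, series_factory):
        series = series_factory(np.full(72 * 40, 22.0))
        anoms = rt.daily_min_anomalies(series, rt.running_mean(series))
        np.testing.assert_allclose(anoms.anomaly, 0.0, atol=1e-12)

    def test_single_cold_sample_sets_the_day_anomaly(self, series_factory):
        values = np.full(72 * 40, 22.0)
        values[72 * 20 + 36] -= 3.0
        series = series_factory(values)
        anoms = rt.daily_min_anomalies(series, rt.running_mean(series))
        assert anoms.anomaly.max() == pytest.approx(3.0, abs=0.01)
        cold_day = series.timestamps[72 * 20].normalize()
        assert anoms.dates[np.argmax(anoms.anomaly)] == cold_day

    def test_matches_bruteforce_recomputation(self):
        series = rt.generate_series(rt.SyntheticConfig(n_days=120, seed=17))
        smoothed = rt.running_mean(series)
        anoms = rt.daily_min_anomalies(series, smoothed)
        rm = pd.Series(smoothed.running_mean, index=series.timestamps)
        got = dict(zip(anoms.dates, anoms.anomaly))
        days = series.timestamps.normalize()
        for day in np.unique(days):
            sel = days == day
            noon_pos = np.flatnonzero(sel)[
                np.argmin(
                    np.abs(
                        series.timestamps[sel] - (day + np.timedelta64(12, "h"))
                    )
                )
            ]
            rm_center = rm.iloc[noon_pos]
            expected = (
                rm_center - np.nanmin(series.temps[sel])
                if np.isfinite(rm_center)
                else None
            )
            if expected is None:
                assert day not in got
            else:
                assert got[day] == pytest.approx(expected, abs=1e-12)

    def test_season_labels(self, series_factory):
        series = series_factory(
            np.full(72 * 70, 20.0), start="2009-04-01"
        )
        anoms = rt.daily_min_anomalies(series, rt.running_mean(series))
        months = anoms.dates.month
        assert np.all(anoms.season[np.isin(months, [5, 6])] == "summer")
        assert np.all(anoms.season[months == 4] == "winter")

    def test_misaligned_smoothed_rejected(self, series_factory):
        a = series_factory(np.full(72 * 40, 22.0))
        b = series_factory(np.full(72 * 41, 22.0))
        with pytest.raises(ValueError, match="aligned"):
            rt.daily_min_anomalies(a, rt.running_mean(b))


class TestDecorrelate:
    def test_stride_one_is_identity(self):
        anoms = rt.AnomalySeries(
            pd.date_range("2009-07-01", periods=10),
            np.arange(10.0),
            np.array(["summer"] * 10),
        )
        out = rt.decorrelate(anoms, stride=1)
        np.testing.assert_array_equal(out.anomaly, anoms.anomaly)

    def test_eight_days_stride_four(self):
        anoms = rt.AnomalySeries(
            pd.date_range("2009-07-01", periods=8),
            np.arange(8.0),
            np.array(["summer"] * 8),
        )
        out = rt.decorrelate(anoms, stride=4)
        np.testing.assert_array_equal(out.anomaly, [0.0, 4.0])

    def test_phase_offsets(self):
        anoms = rt.AnomalySeries(
            pd.date_range("2009-07-01", periods=8),
            np.arange(8.0),
            np.array(["summer"] * 8),
        )
        out = rt.decorrelate(anoms, stride=4, phase=1)
        np.testing.assert_array_equal(out.anomaly, [1.0, 5.0])

    def test_subsampling_removes_ar1_autocorrelation(self):
        # AR(1) with 4-day decorrelation scale: phi^4 ~ 0.04
        rng = np.random.default_rng(23)
        phi, n = 0.45, 4000
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal()
        anoms = rt.AnomalySeries(
            pd.date_range("2009-01-01", periods=n),
            x,
            np.array(["summer"] * n),
        )
        r1_daily = np.corrcoef(x[:-1], x[1:])[0, 1]
        sub = rt.decorrelate(anoms, stride=4).anomaly
        r1 = np.corrcoef(sub[:-1], sub[1:])[0, 1]
        # daily autocorrelation ~ phi; the subsample is indistinguishable
        # from white noise
        assert r1_daily > 0.4
        assert abs(r1) < 0.1


class TestRankExtremes:
    def test_weibull_plotting_positions(self):
        ranked = rt.rank_extremes(
            np.array([3.0, 1.0, 2.0, 5.0, 4.0, 7.0, 6.0, 8.0])
        )
        np.testing.assert_array_equal(ranked.values, np.arange(1.0, 9.0))
        np.testing.assert_allclose(
            ranked.plotting_positions, np.arange(1, 9) / 9.0
        )

    def test_max_position_below_one(self):
        draws = np.random.default_rng(0).uniform(size=100)
        ranked = rt.rank_extremes(draws)
        assert ranked.plotting_positions[-1] == pytest.approx(100 / 101)

    def test_too_few_points_names_n(self):
        with pytest.raises(ValueError, match="n=5"):
            rt.rank_extremes(np.arange(5.0))


class TestEvalProbability:
    def test_mode_identity(self):
        for fit in _random_valid_fits(50, seed=1):
            assert rt.eval_probability(fit, fit.epsilon) == pytest.approx(
                np.exp(-1.0), abs=1e-13
            )

    def test_site16_worked_value(self):
        # independent high-precision route: the same family is a GEV with
        # shape c = beta, loc = epsilon, scale = alpha - beta*epsilon
        p = rt.eval_probability(SITE16, 3.0)
        oracle = stats.genextreme.cdf(
            3.0, SITE16.beta, loc=SITE16.epsilon,
            scale=SITE16.alpha - SITE16.beta * SITE16.epsilon,
        )
        assert p == pytest.approx(oracle, abs=1e-12)
        assert p == pytest.approx(0.9806, abs=2e-4)

    def test_positive_beta_saturates_at_upper_bound(self):
        fit = rt.ExtremeValueFit(1.0, 0.5, 0.5)
        assert rt.eval_probability(fit, 2.0) == 1.0
        assert rt.eval_probability(fit, 5.0) == 1.0

    def test_negative_beta_vanishes_below_lower_bound(self):
        fit = rt.ExtremeValueFit(1.0, -0.5, 0.5)
        assert rt.eval_probability(fit, -2.0) == 0.0  # bound at -2

    def test_monotone_nondecreasing(self):
        xs = np.linspace(-3, 8, 400)
        for fit in _random_valid_fits(20, seed=2):
            p = rt.eval_probability(fit, xs)
            assert np.all(np.diff(p) >= -1e-14)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.3, 2.0),
        b=st.floats(-0.45, 0.45),
        e=st.floats(-0.5, 1.5),
        x=st.floats(-3.0, 8.0),
    )
    def test_agrees_with_gev_oracle(self, a, b, e, x):
        if a - b * e <= 0.05:
            return
        fit = rt.ExtremeValueFit(a, b, e)
        oracle = stats.genextreme.cdf(x, b, loc=e, scale=a - b * e)
        assert rt.eval_probability(fit, x) == pytest.approx(oracle, abs=1e-10)

    def test_invalid_fit_rejected(self):
        with pytest.raises(ValueError, match="alpha - beta"):
            rt.eval_probability(rt.ExtremeValueFit(0.5, 2.0, 1.0), 1.0)


class TestReturnTime:
    def test_tau_at_mode(self):
        for fit in _random_valid_fits(20, seed=3):
            est = rt.return_time(fit, fit.epsilon)
            assert est.tau_days == pytest.approx(TAU_AT_MODE, abs=1e-9)

    @pytest.mark.parametrize(
        "fit, x, printed",
        [
            (SITE16, 3.0, 52),
            (SITE14, 3.0, 14),
            (SITE14, 5.0, 102),
            (SITE10, 2.0, 5),
            (SITE10, 5.0, 42),
        ],
    )
    def test_published_worked_examples(self, fit, x, printed):
        est = rt.return_time(fit, x)
        assert abs(round(est.tau_days) - printed) <= 1

    def test_monotone_in_anomaly(self):
        taus = [rt.return_time(SITE14, x).tau_days for x in (2, 3, 4, 5)]
        assert np.all(np.diff(taus) > 0)

    def test_censoring_over_1000_days(self):
        fit = rt.ExtremeValueFit(0.1, 0.0, 0.2)
        est = rt.return_time(fit, 3.0)
        assert est.censored and est.tau_days > 1000

    def test_censoring_against_record_length(self):
        est = rt.return_time(SITE14, 5.0, record_length_days=90.0)
        assert est.censored  # tau ~ 102 exceeds the 90-day record

    def test_saturated_probability_is_censored_infinite(self):
        fit = rt.ExtremeValueFit(1.0, 0.5, 0.5)
        est = rt.return_time(fit, 3.0)  # beyond the alpha/beta bound
        assert np.isinf(est.tau_days) and est.censored


class TestGumbelLimit:
    def test_small_beta_matches_beta_zero_branch(self):
        a, e = 1.0, 0.5
        xs = np.linspace(e - 3 * a, e + 6 * a, 500)
        p0 = rt.eval_probability(rt.ExtremeValueFit(a, 0.0, e), xs)
        for b in (1e-6, -1e-6):
            pb = rt.eval_probability(rt.ExtremeValueFit(a, b, e), xs)
            rel = np.abs(pb - p0) / np.maximum(p0, 1e-300)
            assert rel.max() < 1e-4


class TestFitExtremeValue:
    def test_noiseless_inversion_recovers_parameters(self):
        a, b, e = 1.0, 0.0, 0.5
        n = 200
        p = np.arange(1, n + 1) / (n + 1)
        x = e - a * np.log(-np.log(p))  # exact Gumbel quantiles
        fit = rt.fit_extreme_value(rt.RankedExtremes(x, p))
        assert fit.alpha == pytest.approx(a, abs=1e-4)
        assert fit.beta == pytest.approx(b, abs=1e-4)
        assert fit.epsilon == pytest.approx(e, abs=1e-4)
        assert fit.residual_norm < 1e-6

    def test_noiseless_inversion_nonzero_beta(self):
        a, b, e = 1.0, -0.2, 0.6
        n = 200
        p = np.arange(1, n + 1) / (n + 1)
        x = (a - (a - b * e) * (-np.log(p)) ** b) / b
        fit = rt.fit_extreme_value(rt.RankedExtremes(x, p))
        assert fit.alpha == pytest.approx(a, abs=1e-3)
        assert fit.beta == pytest.approx(b, abs=1e-3)
        assert fit.epsilon == pytest.approx(e, abs=1e-3)

    def test_mle_route_recovers_parameters(self):
        truth = rt.ExtremeValueFit(1.0, -0.2, 0.6)
        draws = rt.sample_extremes(truth, 5000, seed=31)
        fit = rt.fit_extreme_value(rt.rank_extremes(draws), method="mle")
        assert fit.alpha == pytest.approx(1.0, rel=0.15)
        assert fit.beta == pytest.approx(-0.2, abs=0.1)
        assert fit.epsilon == pytest.approx(0.6, abs=0.1)

    def test_constant_anomalies_rejected(self):
        values = np.full(20, 1.5)
        ranked = rt.RankedExtremes(values, np.arange(1, 21) / 21.0)
        with pytest.raises(ValueError, match="degenerate"):
            rt.fit_extreme_value(ranked)

    def test_unknown_method_rejected(self):
        draws = rt.sample_extremes(rt.ExtremeValueFit(1.0, 0.0, 0.5), 50, 1)
        with pytest.raises(ValueError, match="unknown fit method"):
            rt.fit_extreme_value(rt.rank_extremes(draws), method="magic")

    def test_fit_metadata_carried(self):
        draws = rt.sample_extremes(rt.ExtremeValueFit(1.0, 0.0, 0.5), 100, 2)
        fit = rt.fit_extreme_value(
            rt.rank_extremes(draws), season="summer", site_id=7
        )
        assert (fit.season, fit.site_id, fit.n_points_fit) == ("summer", 7, 100)


class TestMaxExpectedAnomaly:
    def test_inverse_of_return_time(self):
        for fit in (SITE16, SITE14, SITE10):
            x = rt.max_expected_anomaly(fit, 100.0)
            assert rt.return_time(fit, x).tau_days == pytest.approx(
                100.0, rel=1e-9
            )

    def test_site16_period_52_days(self):
        assert rt.max_expected_anomaly(SITE16, 52.0) == pytest.approx(
            3.0, abs=0.02
        )

    def test_positive_beta_approaches_alpha_over_beta(self):
        fit = rt.ExtremeValueFit(1.0, 0.5, 0.5)
        xs = [rt.max_expected_anomaly(fit, T) for T in (10, 100, 1e4, 1e8)]
        assert np.all(np.diff(xs) > 0)
        assert xs[-1] == pytest.approx(1.0 / 0.5, abs=1e-3)
        assert xs[-1] < 1.0 / 0.5

    def test_period_at_or_below_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            rt.max_expected_anomaly(SITE16, 1.5)


class TestReturnTimeTable:
    def test_single_fit_row_shape(self):
        table = rt.return_time_table([SITE14])
        assert len(table) == 1
        row = table.iloc[0]
        assert [row[f"delta_{k}"] for k in (2, 3, 4, 5)] == [
            "5", "14", "38", "102",
        ]
        assert row["alpha"] == pytest.approx(0.942)

    def test_site10_published_row(self):
        row = rt.return_time_table([SITE10]).iloc[0]
        assert [row[f"delta_{k}"] for k in (2, 3, 4, 5)] == [
            "5", "11", "23", "42",
        ]

    def test_all_censored_renders_stars(self):
        fit = rt.ExtremeValueFit(0.1, 0.0, 0.2)
        row = rt.return_time_table([fit]).iloc[0]
        assert [row[f"delta_{k}"] for k in (2, 3, 4, 5)] == ["*"] * 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no fits"):
            rt.return_time_table([])


class TestEmpiricalReturnTimeOracle:
    def test_mean_exceedance_gap_matches_tau(self):
        # i.i.d. daily extremes: the mean gap between successive
        # exceedances of level x is a consistent estimate of the
        # predicted return time 1/(1 - P(x))
        fit = rt.ExtremeValueFit(1.0, -0.2, 0.6)
        x = fit.epsilon + fit.alpha
        draws = rt.sample_extremes(fit, 100_000, seed=12)
        gaps = np.diff(np.flatnonzero(draws > x))
        tau = rt.return_time(fit, x).tau_days
        assert gaps.mean() == pytest.approx(tau, rel=0.10)
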