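"""Synthetic generator: determinism, the deterministic zero-noise climate,
pollutant-temperature coupling, and the within-stratum death-day law."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from etepm import synthetic
from etepm.ete import ETECalendar
import xarray as xr


def _flag_calendar(fields, flag_array):
    da = fields["temperature"]
    flags = xr.DataArray(flag_array, coords=da.coords, dims=da.dims)
    thr = xr.DataArray(np.zeros((da.lat.size, da.lon.size)),
                       coords={"lat": da.lat, "lon": da.lon}, dims=("lat", "lon"))
    from etepm.ete import ETEDefinition
    return ETECalendar(flags=flags, thresholds=thr,
                       definition=ETEDefinition("heat", 95.0, 2))


class TestWeatherGrid:
    def test_same_seed_bit_identical(self, grid_spec):
        a = synthetic.simulate_weather_grid(grid_spec, seed=5)
        b = synthetic.simulate_weather_grid(grid_spec, seed=5)
        for v in a:
            np.testing.assert_array_equal(a[v].values, b[v].values)

    def test_different_seed_differs(self, grid_spec):
        a = synthetic.simulate_weather_grid(grid_spec, seed=5)
        b = synthetic.simulate_weather_grid(grid_spec, seed=6)
        assert not np.array_equal(a["temperature"].values, b["temperature"].values)

    def test_zero_noise_is_exact_sinusoid(self, grid_spec):
        params = synthetic.WeatherModelParams(noise_sd=0.0, rh_noise_sd=0.0,
                                              spatial_gradient=0.0,
                                              pm25_log_sd=0.0)
        f = synthetic.simulate_weather_grid(grid_spec, params, seed=0)
        doy = pd.DatetimeIndex(f.time.values).dayofyear.values
        expected = (params.temp_mean_annual + params.temp_seasonal_amplitude
                    * np.cos(2 * np.pi * (doy - 196.0) / 365.25))
        for i in range(f.lat.size):
            for j in range(f.lon.size):
                np.testing.assert_allclose(f["temperature"].values[:, i, j],
                                           expected, atol=1e-12)

    def test_seasonal_peak_mid_july(self, fields):
        monthly = fields["temperature"].mean(("lat", "lon")) \
            .groupby("time.month").mean()
        assert int(monthly.idxmax("month").values) == 7

    def test_winter_high_pm25_negative_coupling(self, fields):
        t = fields["temperature"].values[:, 0, 0]
        log_pm = np.log(fields["pm25"].values[:, 0, 0])
        assert np.corrcoef(t, log_pm)[0, 1] < -0.1

    def test_bounds_and_positivity(self, fields):
        assert np.all(fields["pm25"].values > 0)
        assert np.all(fields["o3"].values > 0)
        rh = fields["relative_humidity"].values
        assert rh.min() >= 0.0 and rh.max() <= 100.0

    def test_nonfinite_parameter_named_in_error(self, grid_spec):
        params = synthetic.WeatherModelParams(noise_sd=np.nan)
        with pytest.raises(ValueError, match="noise_sd"):
            synthetic.simulate_weather_grid(grid_spec, params, seed=0)

    def test_ar1_out_of_range_rejected(self, grid_spec):
        with pytest.raises(ValueError, match="ar1"):
            synthetic.simulate_weather_grid(
                grid_spec, synthetic.WeatherModelParams(ar1_coefficient=1.0), 0)


class TestCohort:
    def test_same_seed_identical(self, grid_spec, fields, calendars):
        eff = synthetic.TrueEffectSpec()
        a = synthetic.simulate_cohort(500, grid_spec, fields, *calendars, eff, seed=9)
        b = synthetic.simulate_cohort(500, grid_spec, fields, *calendars, eff, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_null_effects_uniform_within_stratum(self, grid_spec, fields, calendars):
        # with zero effects the death day must be uniform over its stratum:
        # chi-square GOF on the within-stratum rank of the death day
        subjects = synthetic.simulate_cohort(10000, grid_spec, fields,
                                             *calendars,
                                             synthetic.TrueEffectSpec(), seed=21)
        death = pd.DatetimeIndex(subjects["death_date"])
        ranks = []
        sizes = []
        for d in death:
            month_days = pd.date_range(d.replace(day=1),
                                       d.replace(day=d.days_in_month), freq="D")
            same = month_days[month_days.weekday == d.weekday()]
            ranks.append(list(same).index(d))
            sizes.append(len(same))
        ranks, sizes = np.array(ranks), np.array(sizes)
        # condition on stratum size to keep the null exactly uniform
        for size in (4, 5):
            obs = np.bincount(ranks[sizes == size], minlength=size)
            p = stats.chisquare(obs).pvalue
            assert p > 0.01

    def test_degenerate_effect_selects_event_day(self, grid_spec, fields):
        # flag the 15th of every month: exactly one flagged day in the
        # stratum sharing its weekday, none elsewhere.  An overwhelming
        # effect must then put essentially every matching death on the 15th
        da = fields["temperature"]
        times = pd.DatetimeIndex(fields.time.values)
        flags = np.zeros(da.shape, dtype=bool)
        flags[times.day == 15, :, :] = True
        heat = _flag_calendar(fields, flags)
        cold = _flag_calendar(fields, np.zeros(da.shape, dtype=bool))
        eff = synthetic.TrueEffectSpec(cumulative_log_or_heatwave=10.0,
                                       lag_weight_profile=(1.0,) + (0.0,) * 6)
        subjects = synthetic.simulate_cohort(2000, grid_spec, fields, heat,
                                             cold, eff, seed=22)
        death = pd.DatetimeIndex(subjects["death_date"])
        mid_month = death.to_period("M").to_timestamp() + pd.Timedelta(days=14)
        in_flagged_stratum = death.weekday == pd.DatetimeIndex(mid_month).weekday
        assert in_flagged_stratum.sum() > 100
        assert np.mean(death[in_flagged_stratum].day == 15) > 0.99

    def test_subjects_inside_grid_and_after_burn_in(self, null_cohort, grid_spec):
        assert null_cohort["lon"].between(grid_spec.lon_min, grid_spec.lon_max).all()
        assert null_cohort["lat"].between(grid_spec.lat_min, grid_spec.lat_max).all()
        start = pd.Timestamp(grid_spec.date_start)
        assert (pd.DatetimeIndex(null_cohort["death_date"])
                >= start + pd.Timedelta(days=6)).all()

    def test_lag_profile_validation(self):
        with pytest.raises(ValueError):
            synthetic.TrueEffectSpec(lag_weight_profile=(0.5, 0.5))
        with pytest.raises(ValueError):
            synthetic.TrueEffectSpec(lag_weight_profile=(0.5,) * 7)
        with pytest.raises(ValueError):
            synthetic.TrueEffectSpec(scenario_log_ors=(0.1,) * 5)  # no cutoff

    def test_default_lag_weights_linear_and_normalized(self):
        w = synthetic.default_lag_weights()
        assert w.sum() == pytest.approx(1.0, abs=1e-15)
        np.testing.assert_allclose(np.diff(w, 2), 0.0, atol=1e-15)
        assert np.all(np.diff(w) < 0)
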