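import numpy as np
import pytest
import xarray as xr

from etepm import casecrossover, ete, synthetic, thermal


@pytest.fixture(scope="session")
def grid_spec():
    return synthetic.GridSpec(lon_min=118.0, lon_max=119.0, lat_min=31.0,
                              lat_max=32.0, cell_size=0.5,
                              date_start="2015-01-01", date_end="2017-12-31")


@pytest.fixture(scope="session")
def fields(grid_spec):
    return synthetic.simulate_weather_grid(grid_spec, seed=11)


@pytest.fixture(scope="session")
def hi_grid(fields):
    t = fields["temperature"]
    return xr.DataArray(
        thermal.heat_index(t.values, fields["relative_humidity"].values),
        coords=t.coords, dims=t.dims, name="heat_index")


@pytest.fixture(scope="session")
def calendars(hi_grid):
    heat_def = ete.ETEDefinition("heat", 90.0, 2)
    return (ete.build_ete_calendar(hi_grid, heat_def),
            ete.build_ete_calendar(hi_grid, heat_def.matched()))


@pytest.fixture(scope="session")
def null_cohort(grid_spec, fields, calendars):
    return synthetic.simulate_cohort(3000, grid_spec, fields, calendars[0],
                                     calendars[1], synthetic.TrueEffectSpec(),
                                     seed=12)


@pytest.fixture(scope="session")
def null_matched(null_cohort, calendars, fields):
    df, info = casecrossover.assemble_matched_sets(null_cohort, calendars[0],
                                                   calendars[1], fields)
    return df


@pytest.fixture(scope="session")
def effect_matched(grid_spec, fields, calendars):
    """Matched sets from a cohort with known nonzero effects."""
    eff = synthetic.TrueEffectSpec(
        cumulative_log_or_heatwave=np.log(1.5),
        cumulative_log_or_coldspell=np.log(1.2),
        cumulative_log_or_pm25_per10=np.log(1.02))
    subjects = synthetic.simulate_cohort(8000, grid_spec, fields, calendars[0],
                                         calendars[1], eff, seed=13)
    df, _ = casecrossover.assemble_matched_sets(subjects, calendars[0],
                                                calendars[1], fields)
    return df, eff, subjects
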