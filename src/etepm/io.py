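"""File interfaces: NetCDF / long-CSV grids, calendars, subject tables.

Grids travel as NetCDF (dims time/lat/lon) or long-format CSV
(date, lat, lon, value); event calendars additionally ship their per-cell
thresholds as CSV (lat, lon, threshold).  Subject tables are CSV with
ISO-8601 dates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .ete import ETECalendar, ETEDefinition

__all__ = ["write_fields_netcdf", "read_fields_netcdf", "grid_to_long_csv",
           "long_csv_to_grid", "calendar_to_csv", "calendar_from_csv",
           "thresholds_to_csv", "subjects_to_csv", "subjects_from_csv"]


def write_fields_netcdf(fields: xr.Dataset, path):
    fields.to_netcdf(path)


def read_fields_netcdf(path) -> xr.Dataset:
    return xr.load_dataset(path)


def grid_to_long_csv(da: xr.DataArray, path, value_name: str = "value"):
    df = da.to_dataframe(name=value_name).reset_index()
    df = df.rename(columns={"time": "date"})
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def long_csv_to_grid(path, value_name: str = "value") -> xr.DataArray:
    df = pd.read_csv(path, parse_dates=["date"])
    df = df.set_index(["date", "lat", "lon"]).sort_index()
    da = df[value_name].to_xarray()
    return da.rename({"date": "time"})


def calendar_to_csv(cal: ETECalendar, path):
    grid_to_long_csv(cal.flags.astype(int), path, value_name="flag")


def calendar_from_csv(path, definition: ETEDefinition,
                      thresholds: xr.DataArray = None) -> ETECalendar:
    flags = long_csv_to_grid(path, value_name="flag").astype(bool)
    if thresholds is None:
        thresholds = xr.DataArray(
            np.full((flags.lat.size, flags.lon.size), np.nan),
            coords={"lat": flags.lat, "lon": flags.lon}, dims=("lat", "lon"))
    return ETECalendar(flags=flags, thresholds=thresholds, definition=definition)


def thresholds_to_csv(cal: ETECalendar, path):
    df = cal.thresholds.to_dataframe(name="threshold").reset_index()
    df.to_csv(path, index=False)


def subjects_to_csv(subjects: pd.DataFrame, path):
    subjects.to_csv(path, index=False, date_format="%Y-%m-%d")


def subjects_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["death_date"])
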