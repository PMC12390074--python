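"""Time-stratified referent selection and matched-set assembly.

Each death (case day) is matched to all other days of the same calendar
month sharing its day of week (3 or 4 referents — every month holds exactly
4 or 5 occurrences of each weekday).  The matched set carries lag 0..6
exposure histories for heat-wave flag, cold-spell flag, PM2.5 and O3,
extracted at the subject's residential point, and is the single interface to
the modelling modules (long one-row-per-person-day table).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .ete import ETECalendar, nearest_cell_index

__all__ = ["select_referents", "assemble_matched_sets", "matched_sets_to_csv",
           "matched_sets_from_csv", "LAG_COLUMNS", "EXPOSURE_VARS", "MAX_LAG"]

logger = logging.getLogger(__name__)

MAX_LAG = 6
EXPOSURE_VARS = ("heatwave", "coldspell", "pm25", "o3")
LAG_COLUMNS = {v: [f"{v}_l{l}" for l in range(MAX_LAG + 1)] for v in EXPOSURE_VARS}


def select_referents(case_date) -> list:
    """All days of the case's month sharing its weekday, case day excluded.

    >>> select_referents("2017-10-13")
    [Timestamp('2017-10-06 00:00:00'), Timestamp('2017-10-20 00:00:00'),
     Timestamp('2017-10-27 00:00:00')]
    """
    d = pd.Timestamp(case_date)
    month_days = pd.date_range(d.replace(day=1), d.replace(day=d.days_in_month),
                               freq="D")
    same = month_days[(month_days.weekday == d.weekday()) & (month_days != d)]
    return list(same)


def _stratum_labels(dates: pd.DatetimeIndex) -> np.ndarray:
    return (dates.strftime("%Y-%m") + "-w" + dates.weekday.astype(str)).to_numpy()


def assemble_matched_sets(subjects: pd.DataFrame, heat_calendar: ETECalendar,
                          cold_calendar: ETECalendar, fields: xr.Dataset,
                          max_lag: int = MAX_LAG):
    """Build the long matched-set table for all subjects.

    Parameters
    ----------
    subjects : DataFrame with columns id, death_date, lon, lat (sex/age pass through).
    heat_calendar, cold_calendar : event calendars on the same grid as ``fields``.
    fields : Dataset with at least ``pm25`` and ``o3`` on dims (time, lat, lon).

    Returns
    -------
    (DataFrame, dict)
        Long table with one row per person-day: subject_id, date, is_case,
        stratum and one column per (exposure variable, lag).  The dict counts
        subjects dropped for incomplete lag histories or invalid cells.
    """
    times = pd.DatetimeIndex(fields.time.values)
    t0 = times[0]
    nT = times.size

    death = pd.DatetimeIndex(pd.to_datetime(subjects["death_date"]))
    case_idx = (death - t0).days.to_numpy()
    if np.any(case_idx < 0) or np.any(case_idx >= nT):
        raise ValueError("some death dates fall outside the grid date range")

    ilat, ilon = nearest_cell_index(fields["pm25"], subjects["lon"].to_numpy(),
                                    subjects["lat"].to_numpy())
    nlat, nlon = fields.lat.size, fields.lon.size
    cell = ilat * nlon + ilon

    invalid_cell = (heat_calendar.invalid.values.reshape(-1)
                    | cold_calendar.invalid.values.reshape(-1))
    drop_invalid = invalid_cell[cell]

    # referent day indices per subject: all same-weekday days of the month
    strata = {}
    df_days = pd.DataFrame({"i": np.arange(nT), "y": times.year, "m": times.month,
                            "w": times.weekday})
    for key, grp in df_days.groupby(["y", "m", "w"], sort=False):
        strata[key] = grp["i"].to_numpy()
    keys = list(zip(death.year, death.month, death.weekday))
    set_days = [strata[k] for k in keys]
    n_days = np.array([len(d) for d in set_days])
    assert np.all((n_days >= 4) & (n_days <= 5)), \
        "every month must hold 4 or 5 occurrences of each weekday"

    # drop subjects whose any set day lacks a complete lag history
    min_day = np.array([d.min() for d in set_days])
    drop_lag = min_day - max_lag < 0
    keep = ~(drop_lag | drop_invalid)
    info = {
        "n_subjects": len(subjects),
        "n_dropped_lag_history": int(np.sum(drop_lag & ~drop_invalid)),
        "n_dropped_invalid_cell": int(np.sum(drop_invalid)),
        "n_kept": int(keep.sum()),
    }
    if info["n_kept"] < info["n_subjects"]:
        logger.info("dropped %d/%d subjects (incomplete lag history: %d, "
                    "invalid cell: %d)", info["n_subjects"] - info["n_kept"],
                    info["n_subjects"], info["n_dropped_lag_history"],
                    info["n_dropped_invalid_cell"])

    kept = np.flatnonzero(keep)
    rows_days = np.concatenate([set_days[i] for i in kept])
    counts = n_days[kept]
    rows_subj = np.repeat(kept, counts)
    rows_cell = cell[rows_subj]
    rows_case = rows_days == np.repeat(case_idx[kept], counts)

    def cell_series(da):
        return da.transpose("time", "lat", "lon").values.reshape(nT, -1)

    series = {
        "heatwave": cell_series(heat_calendar.flags).astype(np.int8),
        "coldspell": cell_series(cold_calendar.flags).astype(np.int8),
        "pm25": cell_series(fields["pm25"]),
        "o3": cell_series(fields["o3"]),
    }

    day_labels = _stratum_labels(times)  # one label per calendar day, indexed below
    data = {
        "subject_id": subjects["id"].to_numpy()[rows_subj],
        "date": times[rows_days],
        "is_case": rows_case.astype(np.int8),
        "stratum": day_labels[rows_days],
    }
    for var in EXPOSURE_VARS:
        s = series[var]
        for l in range(max_lag + 1):
            data[f"{var}_l{l}"] = s[rows_days - l, rows_cell]
    out = pd.DataFrame(data)
    if not np.all(np.isfinite(out[[c for v in EXPOSURE_VARS
                                   for c in LAG_COLUMNS[v]]].to_numpy(dtype=float))):
        raise ValueError("missing lagged exposure values in assembled sets")
    return out, info


def matched_sets_to_csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def matched_sets_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])
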