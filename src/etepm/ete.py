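"""Heat-wave / cold-spell detection on gridded daily metrics.

An extreme temperature event (ETE) is defined per grid cell: a heat wave is a
run of at least ``min_run_days`` consecutive days with the thermal metric at
or above a high percentile of that cell's full multi-year distribution; a
cold spell uses a low percentile and the at-or-below comparison.  Twelve
definitions arise from crossing four percentile pairs (90/10, 92.5/7.5, 95/5,
97.5/2.5) with three minimum durations (2, 3, 4 days).

Grids are ``xarray.DataArray`` objects with dims ``(time, lat, lon)`` on a
regular lon/lat grid and one value per calendar day.  Point extraction is by
nearest cell centre (Euclidean distance in degrees, ties broken toward the
smaller coordinate), the natural rule for categorical event flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "ETEDefinition",
    "ETECalendar",
    "HEAT_PERCENTILES",
    "COLD_PERCENTILES",
    "all_definitions",
    "percentile_threshold",
    "detect_runs",
    "build_ete_calendar",
    "extract_at_point",
    "nearest_cell_index",
]

HEAT_PERCENTILES = (90.0, 92.5, 95.0, 97.5)
COLD_PERCENTILES = (10.0, 7.5, 5.0, 2.5)
#: heat percentile -> matched cold percentile (and vice versa)
MATCHED_PERCENTILE = {90.0: 10.0, 92.5: 7.5, 95.0: 5.0, 97.5: 2.5,
                      10.0: 90.0, 7.5: 92.5, 5.0: 95.0, 2.5: 97.5}


@dataclass(frozen=True)
class ETEDefinition:
    """One extreme-temperature-event definition.

    direction : 'heat' or 'cold'; percentile : threshold percentile of the
    cell's metric distribution; min_run_days : minimum consecutive qualifying
    days; metric : which thermal metric the calendar is built on.
    """

    direction: str
    percentile: float
    min_run_days: int
    metric: str = "heat_index"

    def __post_init__(self):
        if self.direction not in ("heat", "cold"):
            raise ValueError(f"direction must be 'heat' or 'cold', got {self.direction!r}")
        valid = HEAT_PERCENTILES if self.direction == "heat" else COLD_PERCENTILES
        if float(self.percentile) not in valid:
            raise ValueError(
                f"percentile {self.percentile} invalid for direction {self.direction!r}"
            )
        if self.min_run_days < 2:
            raise ValueError("min_run_days must be >= 2")
        if self.metric not in ("heat_index", "air_temperature", "apparent_temperature"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def label(self) -> str:
        return f"P{self.percentile:g}_{self.min_run_days}d"

    def matched(self) -> "ETEDefinition":
        """The paired definition in the opposite direction (e.g. P95 <-> P5)."""
        other = "cold" if self.direction == "heat" else "heat"
        return ETEDefinition(other, MATCHED_PERCENTILE[float(self.percentile)],
                             self.min_run_days, self.metric)


def all_definitions(metric: str = "heat_index"):
    """The full 12-pair set of matched (heat, cold) definitions."""
    pairs = []
    for p in HEAT_PERCENTILES:
        for d in (2, 3, 4):
            heat = ETEDefinition("heat", p, d, metric)
            pairs.append((heat, heat.matched()))
    return pairs


@dataclass
class ETECalendar:
    """Per-cell daily event flags plus the definition and thresholds behind them."""

    flags: xr.DataArray            # bool, dims (time, lat, lon)
    thresholds: xr.DataArray       # float, dims (lat, lon), °C
    definition: ETEDefinition
    invalid: xr.DataArray = field(default=None)  # bool (lat, lon): cells with missing days

    def __post_init__(self):
        if self.invalid is None:
            self.invalid = xr.zeros_like(self.thresholds, dtype=bool)


def percentile_threshold(series, percentile: float) -> float:
    """Linear-interpolation percentile of a full multi-year daily series."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("series is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return float(np.percentile(arr, percentile, method="linear"))


def detect_runs(exceed_flags, min_run_days: int):
    """Mark days lying inside maximal consecutive exceedance runs of length
    >= min_run_days.  Runs are truncated at the series boundaries."""
    f = np.asarray(exceed_flags, dtype=bool)
    if f.ndim != 1:
        raise ValueError("exceed_flags must be 1-D")
    if f.size == 0:
        return f.copy()
    # run-length encode
    padded = np.concatenate(([False], f, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    out = np.zeros_like(f)
    for s, e in zip(starts, ends):
        if e - s >= min_run_days:
            out[s:e] = True
    return out


def build_ete_calendar(metric_grid: xr.DataArray, definition: ETEDefinition) -> ETECalendar:
    """Per-cell percentile threshold plus run detection over the whole grid.

    Cells with any missing (NaN) day are marked invalid; extraction from an
    invalid cell raises.
    """
    da = metric_grid.transpose("time", "lat", "lon")
    vals = da.values  # (T, nlat, nlon)
    nT, nlat, nlon = vals.shape
    invalid = ~np.all(np.isfinite(vals), axis=0)
    thr = np.full((nlat, nlon), np.nan)
    flags = np.zeros(vals.shape, dtype=bool)
    for i in range(nlat):
        for j in range(nlon):
            if invalid[i, j]:
                continue
            series = vals[:, i, j]
            t = np.percentile(series, definition.percentile, method="linear")
            thr[i, j] = t
            exceed = series >= t if definition.direction == "heat" else series <= t
            flags[:, i, j] = detect_runs(exceed, definition.min_run_days)
    coords2 = {"lat": da.lat, "lon": da.lon}
    return ETECalendar(
        flags=xr.DataArray(flags, coords={"time": da.time, **coords2},
                           dims=("time", "lat", "lon"), name="event"),
        thresholds=xr.DataArray(thr, coords=coords2, dims=("lat", "lon"), name="threshold"),
        definition=definition,
        invalid=xr.DataArray(invalid, coords=coords2, dims=("lat", "lon"), name="invalid"),
    )


def _nearest_1d(coords: np.ndarray, value: float) -> int:
    # coords ascending; argmin returns the first (smaller-coordinate) minimiser,
    # implementing the tie-break toward the smaller coordinate
    return int(np.argmin(np.abs(coords - value)))


def nearest_cell_index(grid_like, lon, lat):
    """(ilat, ilon) of the nearest cell centre(s); vectorized over points.

    Raises if any point falls outside the grid bounding box (cell centres
    padded by half a cell in each direction).
    """
    lats = np.asarray(grid_like.lat.values, dtype=float)
    lons = np.asarray(grid_like.lon.values, dtype=float)
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    half_lat = (lats[1] - lats[0]) / 2 if lats.size > 1 else np.inf
    half_lon = (lons[1] - lons[0]) / 2 if lons.size > 1 else np.inf
    if np.any(lat < lats[0] - half_lat) or np.any(lat > lats[-1] + half_lat) \
            or np.any(lon < lons[0] - half_lon) or np.any(lon > lons[-1] + half_lon):
        raise ValueError("point outside grid bounds")
    # searchsorted-based nearest with tie toward the smaller coordinate
    def near(coords, v):
        idx = np.searchsorted(coords, v)
        idx = np.clip(idx, 1, coords.size - 1) if coords.size > 1 else np.zeros_like(idx)
        lo = np.clip(idx - 1, 0, coords.size - 1)
        hi = np.clip(idx, 0, coords.size - 1)
        pick_hi = np.abs(coords[hi] - v) < np.abs(coords[lo] - v)  # strict: ties go low
        return np.where(pick_hi, hi, lo)
    return near(lats, lat), near(lons, lon)


def extract_at_point(grid, lon: float, lat: float, date) -> float:
    """Value of the nearest cell on the given calendar day.

    ``grid`` is a GridFieldSet variable (DataArray) or an :class:`ETECalendar`.
    """
    if isinstance(grid, ETECalendar):
        ilat, ilon = nearest_cell_index(grid.flags, lon, lat)
        ilat, ilon = int(ilat[0]), int(ilon[0])
        if bool(grid.invalid.values[ilat, ilon]):
            raise ValueError(f"nearest cell ({ilat},{ilon}) invalid for point "
                             f"({lon},{lat}) on {date}")
        da = grid.flags
    else:
        ilat, ilon = nearest_cell_index(grid, lon, lat)
        ilat, ilon = int(ilat[0]), int(ilon[0])
        da = grid
    ts = pd.Timestamp(date)
    times = pd.DatetimeIndex(da.time.values)
    k = times.get_indexer([ts])
    if k[0] < 0:
        raise ValueError(f"date {date} not covered by the grid")
    v = da.values[k[0], ilat, ilon]
    if isinstance(grid, ETECalendar):
        return bool(v)
    if not np.isfinite(v):
        raise ValueError(f"missing value at point ({lon},{lat}) on {date}")
    return float(v)
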