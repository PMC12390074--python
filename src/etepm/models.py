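"""Standard model assemblies over the matched-set table.

The single-exposure model mirrors the main analysis: an ETE strata
cross-basis (levels 0 = neither, 1 = heat wave, 2 = cold spell; natural
cubic spline over lag with 2 interior knots equally spaced on the log-lag
scale) jointly with a PM2.5 linear DLM (per 10 µg/m³, cubic polynomial lag
basis), so each exposure is mutually adjusted for the other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clogit
from .basis import (BasisSpec, ModelDesign, cross_basis, cumulative_effect,
                    lag_knots_log, lag_specific_effect)
from .casecrossover import LAG_COLUMNS, MAX_LAG

__all__ = [
    "default_lag_spec",
    "poly_lag_spec",
    "lagged",
    "ete_levels_lagged",
    "fit_single_exposure_model",
]


def default_lag_spec(max_lag: int = MAX_LAG, plus_one: bool = False) -> BasisSpec:
    """Natural cubic spline over lag 0..max_lag, 2 log-spaced interior knots."""
    return BasisSpec("ncs",
                     interior_knots=tuple(lag_knots_log(max_lag, 2, plus_one)),
                     boundary_knots=(0.0, float(max_lag)), intercept=True)


def poly_lag_spec(max_lag: int = MAX_LAG) -> BasisSpec:
    """Cubic polynomial lag basis {1, l/L, (l/L)^2, (l/L)^3}."""
    return BasisSpec("poly", degree=3, scale=float(max_lag), intercept=True)


def lagged(df: pd.DataFrame, var: str) -> np.ndarray:
    """(n_rows, max_lag+1) lagged values of one exposure variable."""
    return df[LAG_COLUMNS[var]].to_numpy(dtype=float)


def ete_levels_lagged(df: pd.DataFrame) -> np.ndarray:
    """Per-lag ETE level: 0 neither, 1 heat wave, 2 cold spell."""
    hw = lagged(df, "heatwave")
    cs = lagged(df, "coldspell")
    if np.any((hw == 1) & (cs == 1)):
        raise ValueError("heat-wave and cold-spell flags overlap")
    return (hw + 2 * cs).astype(int)


def fit_single_exposure_model(df: pd.DataFrame, include_o3: bool = False,
                              lag_spec: BasisSpec = None,
                              pm_lag_spec: BasisSpec = None):
    """Mutually adjusted ETE + PM2.5 (and optionally O3) conditional fit.

    Returns (FitResult, ModelDesign, effects) where effects holds the
    cumulative odds ratios: 'heatwave', 'coldspell' (event vs neither) and
    'pm25_per10' (per 10 µg/m³).
    """
    lag_spec = lag_spec or default_lag_spec()
    pm_lag_spec = pm_lag_spec or poly_lag_spec()

    levels_lagged = ete_levels_lagged(df)
    # a level never observed (e.g. cold spells in a warm-season subset) would
    # give an identically zero column; drop it and report its effect as None
    present = tuple(lv for lv in (0, 1, 2)
                    if lv == 0 or np.any(levels_lagged == lv))
    design = ModelDesign()
    design.add("ete", cross_basis(levels_lagged,
                                  BasisSpec("strata", levels=present, reference=0),
                                  lag_spec))
    design.add("pm25", cross_basis(lagged(df, "pm25"),
                                   BasisSpec("linear", scale=10.0), pm_lag_spec))
    if include_o3:
        design.add("o3", cross_basis(lagged(df, "o3"),
                                     BasisSpec("linear", scale=10.0), pm_lag_spec))

    res = clogit.fit(design.matrix(), df["subject_id"].to_numpy(),
                     df["is_case"].to_numpy())
    effects = {
        "heatwave": (cumulative_effect(res, design, "ete", 1)
                     if 1 in present else None),
        "coldspell": (cumulative_effect(res, design, "ete", 2)
                      if 2 in present else None),
        "pm25_per10": cumulative_effect(res, design, "pm25", 10.0),
    }
    if include_o3:
        effects["o3_per10"] = cumulative_effect(res, design, "o3", 10.0)
    return res, design, effects


def lag_profile(res, design, block: str, contrast, max_lag: int = MAX_LAG):
    """Lag-specific odds ratios for one contrast, lags 0..max_lag."""
    return [lag_specific_effect(res, design, block, contrast, l)
            for l in range(max_lag + 1)]
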