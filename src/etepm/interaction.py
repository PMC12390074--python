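"""Additive interaction of extreme temperature events with PM2.5.

Person-days are classified per lag day into six mutually exclusive
co-exposure scenarios:

    0  neither event, low PM2.5   (reference)
    1  neither event, high PM2.5
    2  heat wave,  low PM2.5
    3  cold spell, low PM2.5
    4  heat wave,  high PM2.5
    5  cold spell, high PM2.5

"High" means strictly above the cutoff (the case-day median by default).  A
strata cross-basis over the scenario levels yields cumulative odds ratios
per level, from which the additive-interaction indices are computed:

    RERI = OR11 - OR10 - OR01 + 1
    AP   = RERI / OR11
    S    = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))

where OR11 is the co-exposure scenario (4 for heat, 5 for cold), OR10 the
event-only scenario (2 or 3) and OR01 the high-PM-only scenario (1).
Confidence intervals for the indices come from a cluster bootstrap that
resamples matched sets with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clogit
from .basis import BasisSpec, ModelDesign, cross_basis, cumulative_effect
from .casecrossover import MAX_LAG
from .models import default_lag_spec, ete_levels_lagged, lagged

__all__ = [
    "SCENARIO_LEVELS",
    "classify_scenario",
    "scenario_levels_lagged",
    "case_day_pm25_median",
    "fit_scenario_model",
    "reri_ap_s",
    "InteractionEstimate",
    "interaction_indices",
    "bootstrap_interaction",
]

SCENARIO_LEVELS = (0, 1, 2, 3, 4, 5)
#: (OR11 level, OR10 level) per interaction direction; OR01 is always level 1
_DIRECTION_LEVELS = {"heat": (4, 2), "cold": (5, 3)}


def classify_scenario(heat_flag, cold_flag, pm25, cutoff: float):
    """Scenario level 0..5 per person-day (vectorized).

    PM2.5 is 'high' when strictly greater than the cutoff; a day flagged as
    both heat wave and cold spell violates calendar disjointness and raises.
    """
    hw = np.asarray(heat_flag).astype(bool)
    cs = np.asarray(cold_flag).astype(bool)
    pm = np.asarray(pm25, dtype=float)
    if np.any(hw & cs):
        raise ValueError("a day cannot be both heat wave and cold spell")
    high = pm > cutoff
    level = np.zeros(hw.shape, dtype=int)
    level[~hw & ~cs & high] = 1
    level[hw & ~high] = 2
    level[cs & ~high] = 3
    level[hw & high] = 4
    level[cs & high] = 5
    return level if level.ndim else int(level)


def scenario_levels_lagged(df: pd.DataFrame, cutoff: float) -> np.ndarray:
    """(n_rows, max_lag+1) scenario level for each lag day of each person-day."""
    hw = lagged(df, "heatwave")
    cs = lagged(df, "coldspell")
    pm = lagged(df, "pm25")
    return classify_scenario(hw, cs, pm, cutoff)


def case_day_pm25_median(df: pd.DataFrame) -> float:
    """Median lag-0 PM2.5 over case days: the default high/low cutoff."""
    return float(df.loc[df["is_case"] == 1, "pm25_l0"].median())


def fit_scenario_model(df: pd.DataFrame, cutoff: float,
                       lag_spec: BasisSpec = None):
    """Strata cross-basis over the six scenario levels, conditional fit.

    Levels absent from the data are reported with a ``None`` odds ratio and
    excluded from the basis (their indicator would be identically zero).

    Returns (FitResult, ModelDesign, {level: EffectEstimate | None}).
    """
    lag_spec = lag_spec or default_lag_spec()
    levels_lagged = scenario_levels_lagged(df, cutoff)
    present = tuple(lv for lv in SCENARIO_LEVELS
                    if lv == 0 or np.any(levels_lagged == lv))
    design = ModelDesign()
    design.add("scenario", cross_basis(
        levels_lagged, BasisSpec("strata", levels=present, reference=0), lag_spec))
    res = clogit.fit(design.matrix(), df["subject_id"].to_numpy(),
                     df["is_case"].to_numpy())
    ors = {}
    for lv in SCENARIO_LEVELS[1:]:
        ors[lv] = (cumulative_effect(res, design, "scenario", lv)
                   if lv in present else None)
    return res, design, ors


def reri_ap_s(or11: float, or10: float, or01: float):
    """Additive-interaction indices from the three cumulative odds ratios.

    Returns (RERI, AP, S); S is None when its denominator is zero.
    """
    for name, v in (("OR11", or11), ("OR10", or10), ("OR01", or01)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be a positive finite odds ratio")
    reri = or11 - or10 - or01 + 1.0
    ap = reri / or11
    denom = (or10 - 1.0) + (or01 - 1.0)
    s = (or11 - 1.0) / denom if denom != 0.0 else None
    return reri, ap, s


@dataclass
class InteractionEstimate:
    """Scenario odds ratios plus additive-interaction indices with CIs."""

    direction: str
    or11: dict
    or10: dict
    or01: dict
    reri: float
    ap: float
    s: float            # None when undefined
    reri_ci: tuple = None
    ap_ci: tuple = None
    s_ci: tuple = None
    n_bootstrap: int = 0
    seed: int = None
    n_dropped_replicates: int = 0
    warning: str = None

    def as_dict(self) -> dict:
        return {
            "direction": self.direction,
            "or11": self.or11, "or10": self.or10, "or01": self.or01,
            "reri": self.reri, "ap": self.ap, "s": self.s,
            "reri_ci": self.reri_ci, "ap_ci": self.ap_ci, "s_ci": self.s_ci,
            "n_bootstrap": self.n_bootstrap, "seed": self.seed,
            "n_dropped_replicates": self.n_dropped_replicates,
            "warning": self.warning,
        }


def interaction_indices(ors: dict, direction: str) -> InteractionEstimate:
    """Point estimates of RERI/AP/S from a fitted scenario model's ORs."""
    lv11, lv10 = _DIRECTION_LEVELS[direction]
    e11, e10, e01 = ors[lv11], ors[lv10], ors[1]
    if e11 is None or e10 is None or e01 is None:
        raise ValueError(f"scenario level missing for direction {direction!r}")
    reri, ap, s = reri_ap_s(e11.or_, e10.or_, e01.or_)
    return InteractionEstimate(direction=direction,
                               or11=e11.as_dict(), or10=e10.as_dict(),
                               or01=e01.as_dict(), reri=reri, ap=ap, s=s)


def bootstrap_interaction(df: pd.DataFrame, cutoff: float, direction: str,
                          B: int = 1000, seed: int = 0,
                          lag_spec: BasisSpec = None) -> InteractionEstimate:
    """Cluster bootstrap (resampling matched sets) for RERI, AP and S.

    Replicates with non-converged fits, a scenario level missing from the
    resample, or an undefined synergy index are dropped and counted; a
    warning is attached when more than 20% are dropped.  Percentile 95% CIs;
    deterministic given the seed.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    lag_spec = lag_spec or default_lag_spec()
    lv11, lv10 = _DIRECTION_LEVELS[direction]

    levels_lagged = scenario_levels_lagged(df, cutoff)
    present = tuple(lv for lv in SCENARIO_LEVELS
                    if lv == 0 or np.any(levels_lagged == lv))
    for lv in (1, lv10, lv11):
        if lv not in present:
            raise ValueError(f"scenario level {lv} absent from the data")
    cb = cross_basis(levels_lagged, BasisSpec("strata", levels=present, reference=0),
                     lag_spec)
    design = ModelDesign().add("scenario", cb)
    X = cb.matrix
    subj = df["subject_id"].to_numpy()
    is_case = df["is_case"].to_numpy().astype(bool)

    codes, _ = clogit.pd_factorize(subj)
    order = np.argsort(codes, kind="stable")
    Xs, cs_s = X[order], is_case[order]
    sorted_codes = codes[order]
    starts = np.concatenate(([0], np.flatnonzero(np.diff(sorted_codes)) + 1))
    sizes = np.diff(np.concatenate((starts, [Xs.shape[0]])))
    n_sets = starts.size

    point_fit = clogit.fit(Xs, sorted_codes, cs_s)
    ors = {lv: cumulative_effect(point_fit, design, "scenario", lv)
           for lv in present if lv != 0}
    est = interaction_indices({lv: ors.get(lv) for lv in SCENARIO_LEVELS[1:]},
                              direction)

    rng = np.random.default_rng(seed)
    reris, aps, ss = [], [], []
    n_dropped = 0
    # presence check per replicate: any nonzero entry in a level's column block
    level_col = {lv: [j for j, l in enumerate(p for p in present if p != 0) if l == lv]
                 for lv in present if lv != 0}
    K = cb.lag_basis_values().shape[1]
    for _ in range(B):
        pick = rng.integers(0, n_sets, size=n_sets)
        row_counts = sizes[pick]
        rows = np.concatenate([np.arange(starts[s], starts[s] + sizes[s])
                               for s in pick])
        new_sets = np.repeat(np.arange(n_sets), row_counts)
        Xb, cb_case = Xs[rows], cs_s[rows]
        ok = True
        for lv in (1, lv10, lv11):
            j = level_col[lv][0]
            if not np.any(Xb[:, j * K: (j + 1) * K]):
                ok = False
                break
        if not ok:
            n_dropped += 1
            continue
        fb = clogit.fit(Xb, new_sets, cb_case, start=point_fit.beta)
        if not fb.converged:
            n_dropped += 1
            continue
        try:
            o11 = cumulative_effect(fb, design, "scenario", lv11).or_
            o10 = cumulative_effect(fb, design, "scenario", lv10).or_
            o01 = cumulative_effect(fb, design, "scenario", 1).or_
            reri_b, ap_b, s_b = reri_ap_s(o11, o10, o01)
        except ValueError:
            n_dropped += 1
            continue
        if s_b is None:
            n_dropped += 1
            continue
        reris.append(reri_b)
        aps.append(ap_b)
        ss.append(s_b)

    def pct(v):
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    est.reri_ci, est.ap_ci, est.s_ci = pct(reris), pct(aps), pct(ss)
    est.n_bootstrap = B
    est.seed = seed
    est.n_dropped_replicates = n_dropped
    if n_dropped > 0.2 * B:
        est.warning = f"{n_dropped}/{B} bootstrap replicates dropped"
    return est
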