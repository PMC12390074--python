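"""Subgroup comparisons and sensitivity variants.

Subgroup analyses refit the model from scratch on each stratum (sex:
men/women; age: <=80 / >80 years) and compare the two cumulative log-OR
contrasts with the two-sample z statistic

    z = (beta1 - beta2) / sqrt(SE1^2 + SE2^2)

with a two-sided normal p-value.  Sensitivity variants re-run the main or
interaction analysis under a modified specification: two-pollutant O3
adjustment, season restriction (warm: May-October; cold: November-March;
April belongs to neither window and is excluded with a count), the WHO IT3
PM2.5 cutoff of 37.5 µg/m³, and alternative thermal metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interaction import fit_scenario_model, interaction_indices
from .models import fit_single_exposure_model

__all__ = ["SubgroupComparison", "compare_strata", "subgroup_analysis",
           "season_subset", "run_sensitivity", "SENSITIVITY_VARIANTS"]

WARM_MONTHS = (5, 6, 7, 8, 9, 10)
COLD_MONTHS = (11, 12, 1, 2, 3)
SENSITIVITY_VARIANTS = ("two_pollutant_o3", "warm_season", "cold_season",
                        "pm25_cutoff_37.5")


@dataclass(frozen=True)
class SubgroupComparison:
    label_1: str
    label_2: str
    beta_1: float
    se_1: float
    beta_2: float
    se_2: float
    z: float
    p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compare_strata(beta_1: float, se_1: float, beta_2: float, se_2: float,
                   label_1: str = "stratum1", label_2: str = "stratum2") -> SubgroupComparison:
    """Two-sample z-test for equality of two stratum-specific log-ORs."""
    denom = np.sqrt(se_1 ** 2 + se_2 ** 2)
    if denom == 0:
        raise ValueError("both standard errors are zero")
    z = (beta_1 - beta_2) / denom
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return SubgroupComparison(label_1, label_2, beta_1, se_1, beta_2, se_2,
                              float(z), p)


def _subject_attr(df: pd.DataFrame, subjects: pd.DataFrame, col: str) -> pd.Series:
    m = subjects.set_index("id")[col]
    return df["subject_id"].map(m)


def subgroup_analysis(df: pd.DataFrame, subjects: pd.DataFrame, by: str,
                      effect: str = "heatwave", age_cut: float = 80.0):
    """Stratified refits plus the between-stratum z-test on one cumulative effect.

    ``by`` is 'sex' (men vs women) or 'age' (<=age_cut vs >age_cut);
    ``effect`` is 'heatwave', 'coldspell' or 'pm25_per10'.
    """
    if by == "sex":
        grp = _subject_attr(df, subjects, "sex")
        labels = ("men", "women")
        masks = [(grp == g).to_numpy() for g in labels]
    elif by == "age":
        age = _subject_attr(df, subjects, "age")
        labels = (f"age<={age_cut:g}", f"age>{age_cut:g}")
        masks = [(age <= age_cut).to_numpy(), (age > age_cut).to_numpy()]
    else:
        raise ValueError("by must be 'sex' or 'age'")

    fits = {}
    betas = []
    for label, mask in zip(labels, masks):
        sub = df.loc[mask]
        if sub.empty:
            raise ValueError(f"stratum {label!r} is empty")
        res, design, effects = fit_single_exposure_model(sub)
        e = effects[effect]
        if e is None:
            raise ValueError(f"effect {effect!r} unidentifiable in stratum {label!r}")
        fits[label] = {"effect": e.as_dict(), "n_sets": res.n_sets}
        betas.append((e.log_or, e.se))
    cmp = compare_strata(betas[0][0], betas[0][1], betas[1][0], betas[1][1],
                         labels[0], labels[1])
    return {"by": by, "effect": effect, "strata": fits, "comparison": cmp.as_dict()}


def season_subset(df: pd.DataFrame, season: str):
    """Restrict matched sets by the case day's month.

    Returns (subset, n_excluded_april_sets).  The two windows leave April
    unassigned; April case days are excluded from both and counted.
    """
    months = WARM_MONTHS if season == "warm" else COLD_MONTHS
    case = df[df["is_case"] == 1]
    case_month = pd.DatetimeIndex(case["date"]).month
    keep_ids = case.loc[np.isin(case_month, months), "subject_id"]
    n_april = int(np.sum(case_month == 4))
    return df[df["subject_id"].isin(set(keep_ids))], n_april


def run_sensitivity(df: pd.DataFrame, variant: str, cutoff: float = None,
                    direction: str = "heat"):
    """One sensitivity variant over an assembled matched-set table.

    Metric variants (air temperature / apparent temperature in place of the
    heat index) operate upstream of this table: rebuild the event calendars
    on the alternative metric and reassemble before calling the standard
    analysis (see the pipeline module).
    """
    out = {"variant": variant}
    if variant == "two_pollutant_o3":
        res, design, effects = fit_single_exposure_model(df, include_o3=True)
        out["effects"] = {k: (v.as_dict() if v else None) for k, v in effects.items()}
        out["n_sets"] = res.n_sets
    elif variant in ("warm_season", "cold_season"):
        season = variant.split("_")[0]
        sub, n_april = season_subset(df, season)
        if sub.empty:
            raise ValueError(f"no matched sets with case days in the {season} season")
        res, design, effects = fit_single_exposure_model(sub)
        out["effects"] = {k: (v.as_dict() if v else None) for k, v in effects.items()}
        out["n_sets"] = res.n_sets
        out["n_excluded_april"] = n_april
    elif variant == "pm25_cutoff_37.5":
        res, design, ors = fit_scenario_model(df, cutoff=37.5)
        est = interaction_indices(ors, direction)
        out["interaction"] = est.as_dict()
        out["cutoff"] = 37.5
    else:
        raise ValueError(f"unknown variant {variant!r}; known: {SENSITIVITY_VARIANTS}")
    return out
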