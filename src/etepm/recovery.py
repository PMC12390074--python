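"""End-to-end parameter-recovery experiments on synthetic data.

Each experiment simulates gridded weather, builds heat-index event calendars
for one definition pair, draws a cohort whose death days follow known
lag-distributed effects, runs referent selection, matched-set assembly and
the conditional logistic cross-basis fit, and returns the recovered
estimates next to the generating truth.  These are the canonical checks that
the whole pipeline — detection, assembly, basis construction, likelihood —
is correctly specified and unbiased.

Run sizes: the estimates' sampling error scales as 1/sqrt(n_subjects), and
with percentile-based events only a small fraction of matched sets carry
within-stratum exposure contrast, so rare definitions (e.g. P2.5_4d) need
large cohorts for tight recovery.  The defaults below put the recovery
tolerances used in the test suite at roughly 2-2.7 standard errors.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from . import casecrossover, ete, interaction, models, synthetic, thermal

__all__ = ["derive_seeds", "build_study", "recover_single_exposure",
           "recover_interaction", "SINGLE_EXPOSURE_RUNS", "INTERACTION_RUN"]

#: single-exposure recovery runs: definition pair, true cumulative ORs
#: (the target effect plus the two mutually adjusted nuisance effects),
#: which effect is the target, and the cohort size.
SINGLE_EXPOSURE_RUNS = {
    "heatwave_p95_3d": {
        "heat_def": ("heat", 95.0, 3),
        "truth_or": {"heatwave": 1.35, "coldspell": 1.08, "pm25_per10": 1.014},
        "target": "heatwave",
        "n_subjects": 500_000,
    },
    "coldspell_p2.5_4d": {
        "heat_def": ("heat", 97.5, 4),
        "truth_or": {"heatwave": 1.59, "coldspell": 1.18, "pm25_per10": 1.013},
        "target": "coldspell",
        "n_subjects": 1_000_000,
    },
    "pm25_p95_5_3d": {
        "heat_def": ("heat", 95.0, 3),
        "truth_or": {"heatwave": 1.35, "coldspell": 1.08, "pm25_per10": 1.014},
        "target": "pm25_per10",
        "n_subjects": 160_000,
    },
    "heatwave_p97.5_3d": {
        "heat_def": ("heat", 97.5, 3),
        "truth_or": {"heatwave": 1.60, "coldspell": 1.17, "pm25_per10": 1.014},
        "target": "heatwave",
        "n_subjects": 800_000,
    },
}

#: scenario-model recovery: the generator's five scenario odds ratios
#: (levels 1..5) imply RERI = +0.40 for heat wave x high PM2.5 and
#: RERI = -0.20 for cold spell x high PM2.5 at the same time.
INTERACTION_RUN = {
    "heat_def": ("heat", 90.0, 2),
    "scenario_or": (1.2, 1.3, 1.3, 1.9, 1.3),
    "pm25_cutoff": 40.8,
    "n_subjects": 1_200_000,
    "truth_reri": {"heat": 0.40, "cold": -0.20},
}


def derive_seeds(seed: int, n: int):
    """Independent sub-seeds (each < 2^31) from one master seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in state]


def build_study(heat_def_args, effects: synthetic.TrueEffectSpec, n_subjects: int,
                seed: int, grid_spec: synthetic.GridSpec = None,
                weather: synthetic.WeatherModelParams = None):
    """Simulate fields, build the matched-pair calendars, draw the cohort and
    assemble matched sets.  Returns (matched_df, subjects, calendars, fields)."""
    grid_spec = grid_spec or synthetic.GridSpec()
    weather_seed, cohort_seed = derive_seeds(seed, 2)
    fields = synthetic.simulate_weather_grid(grid_spec, weather, seed=weather_seed)
    hi = xr.DataArray(
        thermal.heat_index(fields["temperature"].values,
                           fields["relative_humidity"].values),
        coords=fields["temperature"].coords, dims=fields["temperature"].dims,
        name="heat_index")
    heat_def = ete.ETEDefinition(*heat_def_args)
    heat_cal = ete.build_ete_calendar(hi, heat_def)
    cold_cal = ete.build_ete_calendar(hi, heat_def.matched())
    subjects = synthetic.simulate_cohort(n_subjects, grid_spec, fields,
                                         heat_cal, cold_cal, effects,
                                         seed=cohort_seed)
    df, info = casecrossover.assemble_matched_sets(subjects, heat_cal, cold_cal,
                                                   fields)
    return df, subjects, (heat_cal, cold_cal), fields, info


def recover_single_exposure(run: dict, seed: int) -> dict:
    """One single-exposure recovery experiment.

    Returns the recovered cumulative ORs with CIs, the generating truths and
    the cohort size actually analysed.
    """
    truth = run["truth_or"]
    eff = synthetic.TrueEffectSpec(
        cumulative_log_or_heatwave=np.log(truth["heatwave"]),
        cumulative_log_or_coldspell=np.log(truth["coldspell"]),
        cumulative_log_or_pm25_per10=np.log(truth["pm25_per10"]),
    )
    df, subjects, cals, fields, info = build_study(
        run["heat_def"], eff, run["n_subjects"], seed)
    res, design, effects = models.fit_single_exposure_model(df)
    out = {
        "target": run["target"],
        "n_subjects": info["n_kept"],
        "estimates": {k: e.as_dict() for k, e in effects.items()},
        "truth_or": dict(truth),
        "converged": res.converged,
    }
    e = effects[run["target"]]
    out["recovered_or"] = e.or_
    out["truth"] = truth[run["target"]]
    out["covered"] = bool(e.ci_low <= out["truth"] <= e.ci_high)
    return out


def recover_interaction(seed: int, n_subjects: int = None) -> dict:
    """Scenario-model recovery: fitted RERI for both interaction directions."""
    run = INTERACTION_RUN
    n = n_subjects or run["n_subjects"]
    eff = synthetic.TrueEffectSpec(
        scenario_log_ors=tuple(np.log(run["scenario_or"])),
        pm25_cutoff=run["pm25_cutoff"])
    df, subjects, cals, fields, info = build_study(run["heat_def"], eff, n, seed)
    # the scenario model only reads the event flags and PM2.5 lags; dropping
    # the rest keeps the million-subject fit well inside memory
    df = df.drop(columns=[c for c in df.columns
                          if c.startswith("o3_") or c in ("date", "stratum")])
    del subjects, fields, cals
    res, design, ors = interaction.fit_scenario_model(df, cutoff=run["pm25_cutoff"])
    out = {"n_subjects": info["n_kept"], "converged": res.converged,
           "ors": {lv: (e.as_dict() if e else None) for lv, e in ors.items()},
           "truth_reri": dict(run["truth_reri"]), "matched_df": df}
    for d in ("heat", "cold"):
        est = interaction.interaction_indices(ors, d)
        out[f"reri_{d}"] = est.reri
        out[f"ap_{d}"] = est.ap
        out[f"s_{d}"] = est.s
    return out
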