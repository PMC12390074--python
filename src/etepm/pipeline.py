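"""Full-analysis orchestration: config in, machine-readable report out.

A run executes, per requested ETE definition pair: event detection on the
heat-index grid, matched-set assembly, the mutually adjusted single-exposure
fits, the PM2.5 linearity gate, the six-scenario interaction model with
bootstrap CIs, and attributable-mortality estimates with Monte Carlo eCIs;
then sex/age subgroup comparisons and any requested sensitivity variants.
Every stochastic step is seeded from the config, so two runs with the same
config produce identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import xarray as xr
import yaml

from . import (attributable, casecrossover, clogit, ete, interaction, io,
               models, stratified, synthetic, thermal)
from .recovery import derive_seeds

__all__ = ["RunConfig", "run_full_analysis", "validate_report", "parse_definition"]

logger = logging.getLogger(__name__)


def parse_definition(label: str, metric: str = "heat_index") -> ete.ETEDefinition:
    """'P95_3d' -> the heat-wave definition (cold pair via .matched())."""
    body = label.lstrip("Pp")
    pct_s, run_s = body.split("_")
    pct = float(pct_s)
    direction = "heat" if pct >= 50 else "cold"
    return ete.ETEDefinition(direction, pct, int(run_s.rstrip("d")), metric)


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Either ``simulate`` holds a simulation block (n_subjects plus optional
    grid/weather/effects overrides) or ``fields_path``/``subjects_path``
    point at a NetCDF grid stack and a subject CSV.
    """

    seed: int = 0
    definitions: tuple = ("P95_3d",)
    metric: str = "heat_index"
    max_lag: int = 6
    pm25_cutoff: object = "case_day_median"   # or a number (µg/m³)
    bootstrap_b: int = 0                      # 0 disables bootstrap CIs
    mc_draws: int = 1000
    variants: tuple = ()
    subgroups: tuple = ()                     # subset of ('sex', 'age')
    simulate: dict = field(default_factory=lambda: {"n_subjects": 20000})
    fields_path: str = None
    subjects_path: str = None
    out_dir: str = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["definitions"] = tuple(raw.get("definitions", ("P95_3d",)))
        raw["variants"] = tuple(raw.get("variants", ()))
        raw["subgroups"] = tuple(raw.get("subgroups", ()))
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        for k in ("definitions", "variants", "subgroups"):
            d[k] = list(d[k])
        return d


def _load_inputs(config: RunConfig):
    if config.fields_path is not None:
        fields = io.read_fields_netcdf(config.fields_path)
        subjects = io.subjects_from_csv(config.subjects_path)
        return fields, subjects, None
    sim = dict(config.simulate)
    n = int(sim.pop("n_subjects", 20000))
    grid_spec = synthetic.GridSpec(**sim.pop("grid", {}))
    weather = synthetic.WeatherModelParams(**sim.pop("weather", {})) \
        if "weather" in sim else None
    eff_kwargs = sim.pop("effects", {})
    if "scenario_log_ors" in eff_kwargs and eff_kwargs["scenario_log_ors"]:
        eff_kwargs["scenario_log_ors"] = tuple(eff_kwargs["scenario_log_ors"])
    effects = synthetic.TrueEffectSpec(**eff_kwargs)
    weather_seed, cohort_seed = derive_seeds(config.seed, 2)
    fields = synthetic.simulate_weather_grid(grid_spec, weather, seed=weather_seed)
    return fields, (n, grid_spec, effects, cohort_seed), grid_spec


def _metric_grid(fields: xr.Dataset, metric: str) -> xr.DataArray:
    t = fields["temperature"]
    if metric == "air_temperature":
        return t
    rh = fields["relative_humidity"].values
    if metric == "heat_index":
        vals = thermal.heat_index(t.values, rh)
    elif metric == "apparent_temperature":
        # derive vapour pressure from RH via the Magnus saturation formula;
        # fixed nominal wind speed and pressure when not simulated
        es = 6.112 * np.exp(17.62 * t.values / (243.12 + t.values))  # hPa
        e = es * rh / 100.0
        vals = t.values + 0.33 * e - 0.70 * 2.5 - 4.00
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return xr.DataArray(vals, coords=t.coords, dims=t.dims, name=metric)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the configured analysis; returns (and optionally writes) the report."""
    boot_seed, mc_seed = derive_seeds(config.seed + 1, 2)
    fields, cohort_source, grid_spec = _load_inputs(config)
    metric_grid = _metric_grid(fields, config.metric)

    report = {"seed": config.seed, "config": config.as_dict(),
              "definitions": {}, "subgroups": {}, "sensitivity": {}}

    first_df = None
    subjects = None
    for label in config.definitions:
        heat_def = parse_definition(label, config.metric)
        if heat_def.direction == "cold":
            heat_def = heat_def.matched()
        logger.info("definition %s: building calendars", label)
        heat_cal = ete.build_ete_calendar(metric_grid, heat_def)
        cold_cal = ete.build_ete_calendar(metric_grid, heat_def.matched())

        if subjects is None:
            if isinstance(cohort_source, tuple):
                n, gspec, effects, cohort_seed = cohort_source
                subjects = synthetic.simulate_cohort(
                    n, gspec, fields, heat_cal, cold_cal, effects,
                    seed=cohort_seed)
            else:
                subjects = cohort_source

        df, info = casecrossover.assemble_matched_sets(
            subjects, heat_cal, cold_cal, fields, max_lag=config.max_lag)
        report.setdefault("assembly", info)
        if first_df is None:
            first_df = df

        res, design, effects_hat = models.fit_single_exposure_model(df)
        entry = {
            "effects": {k: (v.as_dict() if v else None)
                        for k, v in effects_hat.items()},
            "n_sets": res.n_sets,
            "converged": res.converged,
            "thresholds": {
                "heat_mean": float(np.nanmean(heat_cal.thresholds.values)),
                "cold_mean": float(np.nanmean(cold_cal.thresholds.values)),
            },
        }

        cutoff = (interaction.case_day_pm25_median(df)
                  if config.pm25_cutoff == "case_day_median"
                  else float(config.pm25_cutoff))
        entry["pm25_cutoff"] = cutoff
        s_res, s_design, ors = interaction.fit_scenario_model(df, cutoff)
        inter = {}
        for d in ("heat", "cold"):
            try:
                if config.bootstrap_b > 0:
                    est = interaction.bootstrap_interaction(
                        df, cutoff, d, B=config.bootstrap_b, seed=boot_seed)
                else:
                    est = interaction.interaction_indices(ors, d)
                inter[d] = est.as_dict()
            except ValueError as exc:
                inter[d] = {"skipped": str(exc)}
                logger.warning("definition %s, direction %s: %s", label, d, exc)
        entry["interaction"] = inter

        case_levels = interaction.scenario_levels_lagged(
            df[df["is_case"] == 1], cutoff)
        attr = {}
        for lab in ("pm25", "heatwave", "coldspell", "heatwave_pm25",
                    "coldspell_pm25"):
            try:
                r = attributable.mc_empirical_ci(
                    case_levels, s_res, s_design, lab,
                    n_draws=config.mc_draws, seed=mc_seed)
                attr[lab] = r.as_dict()
            except ValueError as exc:
                attr[lab] = {"skipped": str(exc)}
        entry["attributable"] = attr
        report["definitions"][label] = entry

    gate = clogit.linearity_gate(
        models.lagged(first_df, "pm25"), first_df["subject_id"].to_numpy(),
        first_df["is_case"].to_numpy(),
        adjust=models.cross_basis(
            models.ete_levels_lagged(first_df),
            models.BasisSpec("strata", levels=(0, 1, 2), reference=0),
            models.default_lag_spec()).matrix)
    report["linearity_gate"] = {"choice": gate["choice"], "p": gate["p"],
                                "chi2": gate["chi2"], "df": gate["df"]}
    logger.info("linearity gate: %s (p=%.3f)", gate["choice"], gate["p"])

    for by in config.subgroups:
        report["subgroups"][by] = stratified.subgroup_analysis(
            first_df, subjects, by)
    for variant in config.variants:
        report["sensitivity"][variant] = stratified.run_sensitivity(
            first_df, variant)

    validate_report(report)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonify)
        logger.info("report written to %s", out / "report.json")
    return report


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _check(instance, schema, path="$"):
    t = schema.get("type")
    if t == "object":
        if not isinstance(instance, dict):
            raise ValueError(f"{path}: expected object")
        for key in schema.get("required", ()):
            if key not in instance:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}")
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            for key, val in instance.items():
                if key not in schema.get("properties", {}):
                    _check(val, extra, f"{path}.{key}")
    elif t == "integer":
        if not isinstance(instance, (int, np.integer)) or isinstance(instance, bool):
            raise ValueError(f"{path}: expected integer")
    elif t == "number":
        if not isinstance(instance, (int, float, np.floating, np.integer)):
            raise ValueError(f"{path}: expected number")
    elif t == "string":
        if not isinstance(instance, str):
            raise ValueError(f"{path}: expected string")
        if "enum" in schema and instance not in schema["enum"]:
            raise ValueError(f"{path}: {instance!r} not in {schema['enum']}")


def validate_report(report: dict):
    """Check a report against the schema shipped with the package."""
    schema = json.loads(
        resources.files("etepm.schemas").joinpath("report_schema.json").read_text())
    _check(report, schema)
    return True
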