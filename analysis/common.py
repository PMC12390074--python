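"""Shared setup for the numbered analysis drivers.

One synthetic study at demonstration scale (20k deaths over a 3-year,
4x4-cell grid) with the generator's effects anchored at the published
cumulative odds ratios, so every driver's output can be read against known
truth.  Results land under results/.
"""

from pathlib import Path

import numpy as np
import xarray as xr

from etepm import casecrossover, ete, synthetic, thermal
from etepm.recovery import derive_seeds

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20150101 % (2 ** 31)
N_SUBJECTS = 20_000

TRUE_OR = {"heatwave": 1.35, "coldspell": 1.10, "pm25_per10": 1.014}


def study(definition="P95_3d", n_subjects=N_SUBJECTS, scenario=None, cutoff=None):
    """Simulate fields, calendars, cohort and matched sets for one definition."""
    RESULTS.mkdir(exist_ok=True)
    spec = synthetic.GridSpec()
    ws, cs = derive_seeds(SEED, 2)
    fields = synthetic.simulate_weather_grid(spec, seed=ws)
    hi = xr.DataArray(
        thermal.heat_index(fields["temperature"].values,
                           fields["relative_humidity"].values),
        coords=fields["temperature"].coords, dims=fields["temperature"].dims,
        name="heat_index")
    from etepm.pipeline import parse_definition
    heat_def = parse_definition(definition)
    heat_cal = ete.build_ete_calendar(hi, heat_def)
    cold_cal = ete.build_ete_calendar(hi, heat_def.matched())
    if scenario is not None:
        eff = synthetic.TrueEffectSpec(scenario_log_ors=tuple(np.log(scenario)),
                                       pm25_cutoff=cutoff)
    else:
        eff = synthetic.TrueEffectSpec(
            cumulative_log_or_heatwave=np.log(TRUE_OR["heatwave"]),
            cumulative_log_or_coldspell=np.log(TRUE_OR["coldspell"]),
            cumulative_log_or_pm25_per10=np.log(TRUE_OR["pm25_per10"]))
    subjects = synthetic.simulate_cohort(n_subjects, spec, fields, heat_cal,
                                         cold_cal, eff, seed=cs)
    df, info = casecrossover.assemble_matched_sets(subjects, heat_cal, cold_cal,
                                                   fields)
    return {"spec": spec, "fields": fields, "hi": hi, "heat_cal": heat_cal,
            "cold_cal": cold_cal, "subjects": subjects, "matched": df,
            "info": info, "effects": eff}
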