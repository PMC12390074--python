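"""Cumulative odds ratios for heat wave, cold spell and PM2.5.

Per definition pair: mutually adjusted conditional logistic fit (ETE strata
cross-basis + PM2.5 linear DLM), the PM2.5 linearity gate, and lag-specific
odds ratios for the primary definition.  The generator's true cumulative
ORs are printed next to the recovered ones.  Writes
results/single_exposure_ors.csv and results/lag_profile_p95_3d.csv.
"""

import pandas as pd

from common import RESULTS, TRUE_OR, study
from etepm import clogit
from etepm.models import fit_single_exposure_model, lag_profile, lagged

rows = []
for definition in ("P90_2d", "P95_3d", "P97.5_3d"):
    s = study(definition)
    res, design, effects = fit_single_exposure_model(s["matched"])
    for k, e in effects.items():
        rows.append({"definition": definition, "exposure": k,
                     "or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high,
                     "true_or": TRUE_OR[k]})
    if definition == "P95_3d":
        gate = clogit.linearity_gate(lagged(s["matched"], "pm25"),
                                     s["matched"]["subject_id"].to_numpy(),
                                     s["matched"]["is_case"].to_numpy())
        profile = pd.DataFrame(
            [{"lag": l, "or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high}
             for l, e in enumerate(lag_profile(res, design, "ete", 1))])
        profile.to_csv(RESULTS / "lag_profile_p95_3d.csv", index=False)

df = pd.DataFrame(rows)
df.to_csv(RESULTS / "single_exposure_ors.csv", index=False)
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nPM2.5 linearity gate: {gate['choice']} (LR p = {gate['p']:.2f}) — "
      "a linear distributed-lag model suffices, as in the generating model")
print("heat-wave lag profile written (weights decline with lag by design)")
print(f"wrote {RESULTS / 'single_exposure_ors.csv'}")
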