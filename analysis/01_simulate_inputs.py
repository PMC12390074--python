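"""Simulate the study inputs: gridded daily weather/pollution and a cohort.

Writes the gridded fields (NetCDF), the heat-index summary, and the subject
table (CSV) under results/data/, and prints the climate summary that the
downstream drivers build on.
"""

import numpy as np

from common import RESULTS, study
from etepm import io

out = RESULTS / "data"
out.mkdir(parents=True, exist_ok=True)

s = study()
fields, subjects = s["fields"], s["subjects"]

io.write_fields_netcdf(fields, out / "fields.nc")
io.subjects_to_csv(subjects, out / "subjects.csv")

print(f"grid: {fields.lat.size} x {fields.lon.size} cells, "
      f"{fields.time.size} days")
for v in ("temperature", "relative_humidity", "pm25", "o3"):
    x = fields[v].values
    print(f"  {v:>18}: mean {x.mean():7.1f}  p5 {np.percentile(x, 5):7.1f}  "
          f"p95 {np.percentile(x, 95):7.1f}")
hi = s["hi"].values
print(f"  {'heat_index':>18}: mean {hi.mean():7.1f}  "
      f"p2.5 {np.percentile(hi, 2.5):7.1f}  p95 {np.percentile(hi, 95):7.1f}")

t = fields["temperature"].values.reshape(fields.time.size, -1).mean(axis=1)
pm = np.log(fields["pm25"].values.reshape(fields.time.size, -1)).mean(axis=1)
print(f"corr(daily mean T, mean log PM2.5) = {np.corrcoef(t, pm)[0, 1]:.2f} "
      "(winter-high PM2.5)")
print(f"cohort: {len(subjects)} deaths, "
      f"{(subjects['sex'] == 'men').mean():.1%} men, "
      f"mean age {subjects['age'].mean():.1f}")
print(f"wrote {out / 'fields.nc'} and {out / 'subjects.csv'}")
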