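# Methods

## Design

The pipeline implements a time-stratified case-crossover analysis. Each
subject contributes one matched set: the case day (date of death) plus all
other days of the same calendar month with the same day of week. Because
every month contains exactly 4 or 5 occurrences of each weekday, sets have
3 or 4 referents; the code asserts this globally. Referent selection is
symmetric (if d' is a referent for d, d is a referent for d'), which makes
the stratum an exchangeable cluster — the unit for the interaction
bootstrap.

Exposures are assessed at the subject's residential point by
nearest-cell-centre lookup (Euclidean in degrees; ties go to the smaller
(lat, lon) cell). Event flags are categorical and cannot be interpolated;
the same rule is used for continuous fields for consistency. Any matched
set with an incomplete lag history (a set day closer than 6 days to the
grid start, or an invalid cell) is dropped whole and counted — a
complete-case rule, no imputation.

## Event detection

A heat wave in a cell is a run of at least `min_run_days` (2, 3 or 4)
consecutive days with the thermal metric **at or above** the cell's 90th /
92.5th / 95th / 97.5th percentile; cold spells use the 10th / 7.5th / 5th /
2.5th percentile and **at or below**. Percentiles are linear-interpolation
quantiles of the cell's full multi-year, all-season daily series. Runs are
defined on consecutive calendar days, truncated at the series boundaries;
a missing day both breaks runs and invalidates the cell. Matched
heat/cold calendars are day-wise disjoint whenever the low threshold is
below the high one (always, for non-degenerate series).

The default metric is the heat index: °F arithmetic internally, °C at the
interface. Temperatures at or below 40 °F pass through unchanged; above
that the simple averaged formula applies, replaced by the Rothfusz
regression (with the low- and high-humidity corrections) when it exceeds
79 °F. The branch handover introduces a documented jump below 1.5 °F,
asserted by a dense scan. The alternative metrics are raw air temperature
and Steadman's apparent temperature `AT = Ta + 0.33 e − 0.70 ws − 4.00`
(vapour pressure e from specific humidity and pressure; when only relative
humidity is simulated, e comes from the Magnus saturation formula with
nominal wind 2.5 m/s).

## Model

The exposure–lag surface is a tensor-product cross-basis over lags 0–6:
row t, column (j, k) is `Σ_l f_j(x_{t−l}) g_k(l)`. Conventions, chosen
where the field's practice varies and fixed here for reproducibility:

* the lag basis carries an intercept column; the exposure basis does not
  (reference absorbed);
* ETE exposure: strata indicators over {neither, heat wave, cold spell};
  lag: natural cubic spline, boundary knots [0, 6], 2 interior knots at
  equal log-lag spacing, i.e. {6^(1/3), 6^(2/3)} ≈ {1.817, 3.302}. The
  alternative log(l+1) placement is a config switch;
* PM2.5: linear per 10 µg/m³ (so reported ORs are per-10); lag: cubic
  polynomial {1, l/6, (l/6)², (l/6)³}, scaled to avoid ill-conditioning.
  The spline-vs-linear choice is made by a likelihood-ratio gate: a
  natural-cubic-spline exposure basis (3 df, interior knots equally spaced
  on the log-exposure scale) against the nested linear basis over the same
  lag spline; p ≥ 0.05 keeps the linear DLM;
* the natural cubic spline uses the standard restricted-cubic
  construction: linear beyond the boundary knots (second derivative zero
  at and outside them), column count = interior knots + 1 (+ intercept).

Matched sets are fit by the exact conditional logistic likelihood (one
case per set makes tie-handling moot). Newton–Raphson with analytic
gradient and observed information, log-sum-exp-stabilised set
denominators, step-halving when a step would lower the log-likelihood,
start at β = 0, cap of 100 iterations. Convergence: max |gradient| below
max(1e-8, 4e-12·(1+|ll|)) — the second term acknowledges that a sum over
millions of person-days has a float64 noise floor proportional to the
log-likelihood's magnitude; for small problems the strict absolute
tolerance governs. Separation (|β| > 15 with a non-vanishing gradient) is
flagged, not silently returned. The covariance is the inverse observed
information; cumulative and lag-specific odds ratios are linear contrasts
with delta-method CIs, and lag-specific log-ORs sum exactly to the
cumulative log-OR.

Single-exposure estimates come from one jointly adjusted model (ETE
strata cross-basis + PM2.5 linear DLM, optionally + an O3 linear DLM for
the two-pollutant variant). Interaction uses a six-level scenario strata
cross-basis: {neither event, low PM2.5} (reference), {neither, high},
{heat, low}, {cold, low}, {heat, high}, {cold, high}, with "high" meaning
strictly above the cutoff — by default the case-day median PM2.5, with
37.5 µg/m³ (the WHO interim target 3) as a variant. RERI, AP and S follow
the standard additive-interaction formulas; S is reported as undefined
when its denominator is zero. CIs for the indices come from a percentile
bootstrap that resamples matched sets (the exchangeable cluster) with
replacement, dropping and counting replicates that fail to converge or
lose a scenario level.

Attributable mortality takes the backward perspective: a death at day t
accumulates its own exposure contributions over days t−6..t, with all
other exposures at reference, giving `EF = 1 − exp(−Σ)` per death;
excess deaths sum the per-death fractions. Using the scenario model's
coefficients makes co-exposure excess (levels {heat, high} / {cold, high})
separable from single-exposure excess. Empirical CIs resample the
coefficient vector from N(β̂, V̂) (covariance symmetrised, eigenvalues
clipped at zero; a clearly non-PSD matrix is rejected).

Subgroup analyses (sex; age ≤ 80 vs > 80) refit from scratch per stratum —
conditional likelihoods share no nuisance structure — and compare one
cumulative log-OR contrast by the two-sample z statistic with a two-sided
normal p-value. The season windows (warm: May–October; cold:
November–March) leave April unassigned; April case days are excluded from
both variants and counted.

## Synthetic data

The generator emulates the statistical structure of the study region's
data, not its physics:

* temperature: annual mean 16 °C + seasonal sinusoid of amplitude 13 °C
  peaking 15 July + latitude gradient (−0.8 °C/degree) + stationary AR(1)
  noise (coefficient 0.75, marginal sd 3.5 °C) — a temperate east-Asian
  climate with persistent synoptic anomalies, which is what makes
  multi-day percentile exceedance runs (heat waves, cold spells) occur;
* relative humidity: mean 70 % + AR(1) noise, clipped to [0, 100];
* PM2.5: log-normal (median ≈ 40 µg/m³, log-sd 0.45) with the log-mean
  shifted by −0.35 × the standardised temperature anomaly — winter-high
  pollution episodes lasting several days; O3 analogous with positive
  coupling (summer-high). All draws flow from one seeded generator;
  fixed seed ⇒ bit-identical fields.

Each synthetic subject receives a uniformly random cell and a uniformly
random (year, month, weekday) stratum; the death day is drawn within the
stratum with probability ∝ exp(η), where η distributes the configured
cumulative log-ORs over lags 0–6 by a weight profile. Because the fitted
model conditions on exactly that stratum, the conditional likelihood is
correctly specified by construction and recovery is unbiased. The default
lag profile is linearly declining, w_l = (10−l)/49 — strongest same-day
effect, attenuating over the week — chosen because a linear-in-lag profile
lies exactly in the span of *both* lag bases (natural spline and
polynomial, each containing intercept and linear terms), so no basis
approximation bias enters the recovery tests. Sexes and ages are drawn
from fixed marginals (52.3 % men; age ~ N(81.9, 15.3²) clipped to
[0, 110]) independent of exposure, making subgroup nulls true by design.

What the generator does **not** emulate: population density (cells are
equally likely), spatially correlated noise between cells, humidity-
temperature dependence, measurement error in exposures, and competing
causes of death. Passing recovery tests therefore demonstrates the
estimators' correctness under a correctly specified design, not robustness
to exposure misclassification or confounding in real registries.

## Problem sizes and precision

Recovery precision is limited by how many matched sets carry
within-stratum exposure contrast; for rare definitions (97.5th/2.5nd
percentile, 3–4-day runs) that is a small fraction of sets. Measured
log-OR standard errors at 40,000 subjects are ≈ 0.05 (heat P95_3d), 0.08
(heat P97.5_3d), 0.10 (cold P2.5_4d) and 0.0037 (PM2.5 per 10); the
recovery experiments therefore use 160k–1.2M subjects, sized so the test
tolerances sit at roughly 2–2.7 standard errors (the additive-interaction
indices, being differences of odds ratios, are the least precise per
subject). The bootstrap coverage check runs at 40,000 subjects with
B = 200 replicates, where a resampled refit costs well under a second.
Null-calibration uses 100 replicates of 2,000 subjects. A full acceptance
run takes a few minutes and peaks near 4.6 GB of memory (the
1.2-million-subject scenario cohort).

## Known limitations

* The conditional-likelihood solver handles one case per set (the
  case-crossover situation); general m:n matching is out of scope.
* Cross-bases are unpenalised; no smoothing parameter selection.
* The attributable decomposition inherits the scenario model's
  classification: a death day misclassified around the PM2.5 cutoff moves
  excess between the single- and co-exposure labels.
* Percentile thresholds use the whole-period all-season distribution; a
  deliberately different climatology (e.g. warm-season-only percentiles)
  requires passing a pre-subset series.
* NetCDF round-trips assume a regular lon/lat grid with a complete daily
  time axis.
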