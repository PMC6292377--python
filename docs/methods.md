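# Methods

## The analysis

`gridocc` implements a procedure for detecting a breeding-range expansion
from citizen-science checklist data. The unit of observation is the
*complete checklist*: a list of every species an observer detected during
one outing, with effort metadata (duration, distance, protocol). Because a
complete checklist licenses the inference "not reported, therefore not
detected", the data can be zero-filled into an explicit
detection/nondetection table for any species of interest.

Raw checklist-level detection rates are a poor index of occurrence for a
rare, localized species: many checklists target the same known individual,
and the overwhelming majority of checklists come from places the species
does not occur. The procedure therefore aggregates to grid-cell occupancy:

1. **Filter** checklists — breeding-season months only (June–July by
   default, when passage migrants are absent), a named county region,
   exclusion of protocols that cannot detect the species (Yard Count, Loon
   Watch, My Yard eBird, Pelagic), complete checklists only, and collapse
   of *group checklists* (several observers sharing one outing, linked by a
   group identifier) to a single record.
2. **Grid** the study area with square cells in a planar equal-area
   projection and record, per cell per year, whether at least one retained
   checklist detected the species, how many checklists were submitted, and
   the summed observation hours.
3. **Model** the binary cell-year occupancy with a binomial GLM (logit
   link): `logit P(occupied) = a + b_year * (year - mean year)`, optionally
   adding the cell-year effort hours as a covariate. The year/year+effort
   choice is made by analysis of deviance; overdispersion is checked via
   the Pearson statistic; control species fitted identically rule out
   observer-behavior artifacts.

`b_year` is a per-year log-odds slope. Both growth-rate conventions are
reported: `100*b` ("percent per year" on the log-odds scale) and
`100*(exp(b)-1)` (percent change in odds per year); they agree to first
order for small `b`.

## Model fitting

Fitting is by iteratively reweighted least squares to a deviance-change
tolerance of 1e-8 with at most 100 iterations. Responses that are all-0 or
all-1 are reported as degenerate (no coefficient table); complete
separation (every observation fitted essentially perfectly, so the MLE
diverges) is detected and flagged with `converged = False` rather than
silently reported. Year is centered before fitting, which affects only the
intercept. Cell-years with constant outcome in early years (e.g. an
unoccupied species) are legitimate rows and are never dropped.

The likelihood-ratio (analysis-of-deviance) statistic between nested fits
is the deviance difference referred to chi-square with df equal to the
difference in coefficient count. The overdispersion statistic is the sum
of squared Pearson residuals `(y - p)^2 / (p(1-p))`; its ratio to the
residual degrees of freedom should be near 1 under the Bernoulli
assumption, and overdispersion is flagged when the upper-tail chi-square
probability is below 0.05.

Confidence intervals default to profile likelihood: the interval is the
set of slope values whose profile deviance (other coefficients refit) lies
within the chi-square(1) quantile of the minimum, inverted by bisection to
1e-6 on the coefficient scale; Wald intervals are also available, and are
the fallback when a profile bound cannot be bracketed. The Wald z test on
the slope is the headline p-value, with the LRT p reported alongside.

## Geometry

"10 km grid" is read as square cells of 10 km side (the conventional GIS
usage); a literal-area reading (side `sqrt(10)` km) is selectable. The
planar CRS is a spherical Albers equal-area conic with the conterminous-US
parameterisation (standard parallels 29.5/45.5, origin 23N 96W, authalic
radius), implemented in closed form; equal-area cells keep occupancy
comparable across a study region that spans UTM zones. Cells are half-open
`[low, high)` on both axes, so assignment is a true partition.

Grid origins are snapped down to the lattice of whole multiples of the
cell side rather than placed at the exact minimum point. This makes the
grid independent of which checklist happens to be westernmost (adding one
point cannot shift every cell boundary) and makes the 10-km and 5-km grids
nest exactly, which the sensitivity re-analysis relies on. A data-derived
origin is also statistically worse: detections leaking across the offset
cell boundaries create phantom occupied cells at a rate that grows with
checklist density, which inflates the estimated year slope when effort
grows over time.

Traveling checklists are assigned to the single cell containing their
reported point; track length is ignored (a known limitation of
point-referenced checklist data). Elevation is sampled per point by
nearest cell from a single-band raster in ESRI ASCII grid format, with
out-of-bounds and no-data points reported as missing, and summarized as
median and range per region label.

## The synthetic generator

Because real extracts are proprietary, validation runs on a generator that
emulates the assumed statistical structure end to end. Defaults (the study
conditions used throughout the tests):

| parameter | default | why |
|---|---|---|
| years | 2003–2016 | 14-year series matching the analysis window |
| cells | 300 of 10 km side | a two-state study region at desk scale |
| baseline logit occupancy | -4.0 | ~1.8% occupancy in year 1, rising to ~15% — brackets the observed 0%–8.7% range for a rare, expanding species |
| `b_year_true` | 0.18 | the trend magnitude of interest |
| detection probability | 0.95 per checklist | a conspicuous, actively sought singing species; keeps apparent occupancy close to latent occupancy so recovery isolates estimation error |
| effort | Poisson, 3 checklists/cell in year 1, ×1.25/yr | ~78,000 checklists over the series, matching the scale of a real extract whose effort hours grew ~20-fold |
| duration | Normal(1.5 h, 1 h), floor 0.05 | typical checklist lengths |
| group probability | 0.10 | one duplicate copy per group |
| excluded-protocol probability | 0.02 | a small contaminating fraction |
| controls | flat (baseline -2.5) and slightly declining (-0.03/yr, baseline -1.5) | the two control-species patterns |

Each cell-year is latently occupied with probability
`logistic(base + b*t)`; each checklist in an occupied cell-year detects
the species independently with the detection probability; group
duplicates copy an existing checklist verbatim under a shared group id;
coordinates are uniform within cells, and a synthetic county map
partitions the grid into the eight default region counties so the regional
filter is exercised. All randomness flows from a single seed and output is
byte-identical across equal seeds.

**Latent vs apparent occupancy.** Detection is conditional on latent
occupancy, so the pipeline estimates the trend in *apparent* (detected)
occupancy. The apparent estimand is computed analytically
(`SyntheticConfig.apparent_slope`): apparent occupancy is
`q_t = logistic(base + b t) * P(at least one detection | occupied,
surveyed)` under Poisson checklist counts, and the estimand is the slope
of the logistic curve closest to `q_t` in survey-weighted KL divergence —
the value the GLM converges to as the number of cells grows. At the
defaults this is 0.1803/yr, i.e. a drift of +0.0003 above the latent
slope, shrinking as effort grows. Recovery summaries report bias and
coverage against both targets. Any small remaining mean bias beyond the
drift is the familiar finite-sample (away-from-zero) bias of the logistic
MLE at a few hundred events, which any maximum-likelihood fit of this
model shares.

What the generator does **not** emulate: spatial autocorrelation of
occupancy, observer-skill heterogeneity, within-season turnover, traveling
tracks crossing cells, and non-June/July dates. Passing tests therefore
demonstrate correctness of the pipeline under the stated generative model,
not robustness of the method to those real-data features.

## Problem sizes used in validation

The recovery and calibration experiments use 500 replicates at the default
conditions (the acceptance test suite) and 150 replicates in the
acceptance script; 500 replicates give a Monte-Carlo SE of ~0.0008 on the
mean slope and ~1% on coverage. Oracle-equivalence checks (direct
numerical likelihood maximization, brute-force filter/grid scans) run on
instances of up to a few hundred rows, where exhaustive comparison is
exact.

## Known limitations

- County matching is attribute-based, not spatial; records with missing
  counties are dropped (and counted) by the region filter.
- The profile interval falls back to Wald with a warning near separation.
- Pearson overdispersion on sparse Bernoulli data is a coarse diagnostic;
  the test is reported, not used to adjust standard errors.
- The dedup tie-break inside a group (maximal focal count, then smallest
  checklist id) is a deterministic convention for reproducibility; any
  member would be equally valid when detections agree.
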