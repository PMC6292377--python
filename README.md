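# gridocc

Grid-cell occupancy trend analysis for citizen-science checklist data.

`gridocc` is for ornithologists and ecologists who want to quantify a
range shift — such as a breeding-range expansion — from eBird-style
checklist extracts, where raw detection rates are confounded by uneven and
growing observer effort and by repeated visits to known individuals. It
implements the full procedure as a reusable, tested pipeline:

1. **Zero-filling** — complete checklists are expanded so every
   (checklist, species) pair carries an explicit present/absent record.
2. **Filtering** — breeding-season window (June–July), a configurable
   county region, exclusion of unsuitable survey protocols ("Yard Count",
   "Loon Watch", "My Yard eBird", "Pelagic"), complete checklists only,
   and deduplication of shared group checklists, with exact per-stage
   bookkeeping.
3. **Gridding** — checklists are projected to an equal-area planar CRS and
   aggregated on a square grid (10 km cells by default, 5 km for
   sensitivity analysis) into per-cell-per-year occupancy, checklist
   counts and summed effort hours.
4. **Trend model** — a binomial GLM of cell-year occupancy on year,

   logit P(occupied in cell i, year t) = a + b_year (t − t̄) [+ b_eff effort_it],

   with analysis of deviance between the year and year+effort models,
   an overdispersion test on the Pearson statistic, Wald and
   profile-likelihood confidence intervals, growth-rate summaries on both
   conventions (100·b and 100·(e^b − 1) percent per year), co-occurrence
   rates, and control-species contrasts.
5. **Synthetic data** — a generator that simulates checklist datasets with
   known latent occupancy trend, imperfect detection, growing effort,
   group duplicates and excluded protocols, so every stage and the
   estimator's recovery properties are testable without any download.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a 14-year, 300-cell dataset at the default study conditions
(focal trend 0.18/yr on the log-odds scale, one flat and one slightly
declining control species) and run the full pipeline:

```python
import gridocc as g

cfg = g.SyntheticConfig(seed=0)          # ~86,000 checklists, 2003-2016
ds = g.simulate_dataset(cfg)
res = g.analyze_simulated(ds)            # filters -> 10 km grid -> GLM

fit, ci = res["fox_sparrow"]
print(f"b_year = {fit.coef('year'):.3f}, "
      f"95% profile CI [{ci.lower:.3f}, {ci.upper:.3f}]")
```

prints

```
b_year = 0.162, 95% profile CI [0.129, 0.196]
```

i.e. this realization estimates a 16.2% per-year increase (log-odds
convention; `g.annual_growth(fit)` also reports the odds-ratio convention,
here 17.6%/yr) — a draw consistent with the generating 0.18 given the
replicate SD of ~0.017. The controls come out flat and slightly negative
(`bicknells_thrush` 0.000 [−0.028, 0.029], `blackpoll_warbler` −0.025
[−0.046, −0.004]), and the overdispersion ratio is 1.016 (p = 0.24), so
the binomial assumption stands.

The same run from the shell, via the CLI:

```sh
gridocc simulate -o sim --seed 0          # checklists.tsv + truth.csv
gridocc run -c run.yaml                   # full pipeline from a YAML config
gridocc report -i out/report.json         # species contrast table
```

`gridocc filter`, `gridocc grid` and `gridocc fit` expose the individual
stages for use on real EBD-style extracts.

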