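# cranecycle

Annual-cycle analysis for long-distance migratory waterbirds, built around
the kind of multi-year dataset a crane conservation program collects:
GPS/Argos tracking fixes, territory-level nest records, colour-band
resighting histories, and site-by-year environmental series.  The package
chains the standard analyses of such a program into one tested pipeline:

- **Track preprocessing** — location-error filtering (fixes with error
  > 100 m dropped), greedy thinning to a 2-h fix interval, great-circle
  step metrics.
- **Migration phenology** — fixes above 47°N are on the breeding grounds
  and below 29.3°N on the wintering grounds; each crossing between the two
  regions is a migration event with departure date, arrival date and
  duration.
- **Stopover detection** — stationary fixes (step < 10 km, ground speed
  ≈ 0) clustered by complete-linkage agglomeration on the great-circle
  distance matrix, cut at 50 km; clusters where a bird stayed ≥ 2 days are
  stopover sites.
- **Breeding-performance GLMs** — binomial GLMs of occupancy / clutch size
  / hatching success on scaled covariates, VIF > 3 exclusion, all-subsets
  fitting with Akaike weights w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2),
  full-model averaging with Burnham–Anderson unconditional SEs, and a
  ΔAIC ≤ 2 top model set.
- **Bayesian survival** — an age-structured Cormack–Jolly–Seber model:
  latent alive states z_{i,t}, apparent survival Φ split by age class
  (juvenile for the first two annual intervals after a 1-May hatch) and
  year, and a year-specific resighting probability p shared by both ages.
  Fitted by a Gibbs sampler (conjugate Beta updates under Uniform(0,1)
  priors), 3 chains × 10,000 iterations, last 5,000 thinned by 6,
  convergence accepted when all identifiable R̂ < 1.02.
- **Environmental trends** — water as % of site maximum, absolute
  anomalies from the long-term mean, proportional change vs. a reference
  year, and correlation-matrix PCA of the seasonal covariate set.

A synthetic-data module (`cranecycle.synth`) generates all four data types
with known ground truth, so every stage is testable without any field data.

## Worked example

```python
import numpy as np
from cranecycle import synth, tracks, phenology, stopover, survival

# 1. simulate a small tagging program: 4 birds, 2 annual round trips
cfg = synth.TrackSimConfig(n_individuals=4, years=(2015, 2016),
                           gps_noise_m=25.0, argos_fraction=0.25, seed=7)
trk, truth = synth.simulate_tracks(cfg)
print(f"{len(trk)} raw fixes from {cfg.n_individuals} birds")

# 2. preprocess: drop fixes with >100 m error, thin to one fix per 2 h
pre = tracks.preprocess(trk, max_error_m=100, interval_h=2)
print(f"{len(pre)} fixes after error filter + 2-h thinning")

# 3. migration events and stopovers
det = stopover.StopoverDetector(cut_km=50, min_days=2).fit(pre)
events = stopover.assign_stops_to_events(phenology.extract_events(pre),
                                         det.stopovers_)
print(phenology.summarize_events(events)[
    ["direction", "n", "duration_days_median", "duration_days_min",
     "duration_days_max"]].to_string(index=False))

# 4. Bayesian CJS survival on a simulated marking program
ccfg = synth.CJSSimConfig(seed=7)   # 282 juveniles + 36 adults, 7 cohorts
hist = synth.simulate_capture_histories(ccfg)
m = survival.BayesianCJS(random_state=7).fit(hist, ccfg.occasions)
ann = m.annual_survival_
print(f"converged: {m.converged_}")
print(f"mean adult survival:    {ann[ann.age=='adult']['median'].mean():.2f}")
print(f"mean juvenile survival: {ann[ann.age=='juvenile']['median'].mean():.2f}")
```

prints

```
31149 raw fixes from 4 birds
23220 fixes after error filter + 2-h thinning
 direction  n  duration_days_median  duration_days_min  duration_days_max
northbound  8                  26.5               26.0               27.0
southbound  8                  18.0               18.0               19.0
converged: True
mean adult survival:    0.83
mean juvenile survival: 0.78
```

Every bird completes one southbound and one northbound journey per tracked
year (4 birds × 2 years × 2 directions = 16 events); durations reflect the
simulator's planned staging bouts (long staging on the northbound leg, so
northbound migration is slower).  The CJS fit recovers the generating
survival probabilities (juvenile 0.76, adult 0.84) from the resighting
histories alone, and the convergence flag certifies that every
identifiable parameter's Gelman–Rubin R̂ is below 1.02.

A `cranecycle` console script exposes the same pipeline from the shell
(`cranecycle simulate`, `preprocess`, `phenology`, `stopover`,
`breeding-fit`, `survival-fit`, `trends`); see `cranecycle --help`.

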