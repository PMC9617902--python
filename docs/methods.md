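# Methods

This note records the models implemented in `cranecycle`, the conventions
chosen where the underlying field practice is ambiguous, and what the
synthetic-data tests do and do not demonstrate.

## Track preprocessing

Fixes are timestamped WGS84 positions with a device-reported location
error in metres.  The error filter drops fixes whose error *strictly
exceeds* 100 m; fixes with missing error are retained, on the view that
only known-bad positions should be excluded.  Temporal regularization is
greedy subset selection — keep the first fix, then the earliest fix at
least `interval − tolerance` (default 2 h − 0.25 h) after the last kept
fix — never interpolation, so every output fix is a real observation.
All distances are haversine great-circle distances on a sphere of radius
6371.0088 km (the IUGG mean radius, fixed so results are bit-reproducible).
Timestamps are treated as UTC throughout and calendar dates are UTC dates.

## Migration phenology

Two latitude thresholds partition the range: breeding strictly above
47°N, wintering strictly below 29.3°N, transit between (boundary values
are transit).  A migration event is a crossing between the terminal
regions in the time-ordered fix sequence.  Conventions, each chosen once:

- **Departure** is the date of the *last* fix inside the origin region
  before the crossing (robust to fix gaps), arrival the date of the first
  fix inside the destination region.
- **Duration** is the whole-day difference of the two UTC dates.
- **Season year** is the departure year for southbound events and the
  arrival year for northbound events.
- Brief re-entries into the origin region cannot split an event: an event
  exists only between consecutive visits to the two different terminal
  regions, so any intermediate return simply moves the departure date.

Sub-day precision of departure and arrival is not attempted; real
programs report integer days and fix gaps make finer claims spurious.

## Stopover detection

A fix is *stationary* when its incoming step is shorter than 10 km
(strict) and its ground speed is at most `speed_epsilon` km/h.  A literal
zero-speed rule is unattainable with noisy positions: two fixes at the
same true location with position noise σ produce an apparent speed of
about σ√2/Δt (≈ 0.35 km/h for σ = 500 m at 2-h fixes).  The default
epsilon, 0.1 km/h, suits clean GPS (σ ≈ 25 m ⇒ apparent speed
≈ 0.02 km/h); analyses of noisier data should raise epsilon above the
noise speed (the 500-m-noise tests use 1 km/h).  Epsilon 0 recovers the
strict rule.

Stationary fixes outside the two terminal regions are clustered by
agglomerative clustering on the pairwise great-circle distance matrix
with the dendrogram cut at 50 km.  *Complete* linkage is the default
because it alone guarantees the proximity interpretation of the cut:
every within-cluster pairwise distance is ≤ 50 km (asserted in tests);
single linkage is available for sensitivity analysis.  Because a bird can
pass the same site on both legs of the round trip, a spatial cluster's
members are split into temporally contiguous *visits* wherever
consecutive member fixes are more than `visit_gap_days` (default 1 day)
apart; dwell is measured per visit, and visits with dwell ≥ 2 days are
stopovers.  Note a discretization bound: a stay of exactly D days sampled
every h hours is observed as ≥ D − h/24 days, so planned stays right at
the 2-day threshold straddle it; recovery tests plant stays of ≥ 3 days.

Per-individual detection is the default.  Site-level (pooled) counts use
two-stage pooling: per-individual visit centroids are re-clustered with
the same 50-km complete-linkage cut.  This is memory-light at
many-individual scale and preserves the proximity rule; a pooled site's
dwell for thresholding is its longest single visit, and its reported mean
stay is the mean over visits.

Each stopover is assigned to the migration event whose
[departure, arrival] window contains its first-seen instant, so a stay
straddling the arrival date belongs to the event in which it began.

## Breeding-performance GLMs and model averaging

Predictors are standardized to mean 0, sd 1 (divisor n − 1) so effect
sizes are comparable.  Collinearity screening is iterative: VIF_j =
1/(1 − R²_j) from an intercept-included OLS of predictor j on the others;
while any VIF exceeds 3 the worst column is dropped (perfect collinearity
counts as infinite VIF).  The largest absolute pairwise correlation is
reported against a 0.7 cut-off.

Single fits use statsmodels GLM (IRLS, tolerance 1e-8, ≤ 100 iterations)
with a logit link for binary responses and an identity link for the
Gaussian family used by day-of-year and duration responses.  Complete
separation is flagged and the fit marked non-converged but retained.
AIC is −2·loglik + 2k with k the number of estimated regression
coefficients (for the Gaussian family the log-likelihood is maximized
with σ² profiled at its MLE; the constant offset from not counting σ²
cancels in ΔAIC within a family).

All 2^p predictor subsets are fitted with the intercept always included
(capped at p = 15).  Akaike weights are w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)
over all subsets.  *Full-model* averaging is the default — a term absent
from a model contributes β = 0 — with the Burnham–Anderson unconditional
standard error Σ w_i √(se_i² + (β_i − β̄)²).  The top model set is
inclusive at the ΔAIC = 2 boundary.  Plain AIC is the default criterion;
the small-sample AICc correction is available (`aicc=True`) since n/k is
small for some annual models.

## Bayesian Cormack–Jolly–Seber survival

Encounter histories are 0/1 vectors over annual occasions, starting with
a 1 at marking.  The state-space model: latent alive indicator
z_{i,t+1} | z_{i,t}=1 ~ Bernoulli(Φ_{a(i,t),t}), detection
y_{i,t} | z_{i,t}=1 ~ Bernoulli(p_t) at occasions after marking.  The
"fixed age effect" is implemented as separate juvenile and adult survival
series per interval (age × year); birds marked as chicks are juvenile for
the two annual intervals after the 1-May hatch year, adult thereafter.
Resighting probability is year-specific and shared by the age classes.

Priors are Uniform(0,1) on every Φ and p.  The sampler is Gibbs: alive
states after an individual's last sighting are updated from their full
conditionals in a single-site sweep (absorbing death, so the sweep cannot
create invalid paths), and every Φ and p then has a conjugate Beta full
conditional given the states.  Chains are initialized from independent
prior draws; the same seed yields bit-identical draws (chains are seeded
by `SeedSequence.spawn`).  Defaults: 3 chains × 10,000 iterations,
burn-in 5,000, thinning 6 — each chain keeps ⌈5000/6⌉ = 834 draws,
2,502 per parameter.  Convergence is monitored with the Gelman–Rubin
statistic R̂ = √(((n−1)/n·W + B/n)/W); a fit is accepted when all
*identifiable* parameters have R̂ < 1.02.  The final-interval Φ and
final-occasion p are confounded in any CJS model (only their product is
likelihood-identified); they are reported but flagged
`identifiable=False` rather than hidden.  The marginal likelihood
(forward recursion with the χ never-seen-again terms) is implemented
independently of the sampler and is verified against brute-force
latent-path enumeration for all histories of length ≤ 6.

Annual survival estimates are related to environmental variation by
reusing the Gaussian-family all-subsets averager with principal-component
scores as predictors, one run per age class; with few years and five PCs
the full model is rank-marginal, which the code flags.

## Environmental trends and PCA

Water series are expressed as a percentage of the site's historical
maximum (max ↦ 100, scale-invariant); temperature and precipitation as
absolute anomalies from the long-term mean (mean ↦ 0, idempotent); human
density as proportional change against year 2000 (reference ↦ 1).  PCA is
performed on the *correlation* matrix — the covariate set mixes °C, mm, %
and persons/km², so covariance PCA would be dominated by units — via SVD
of the standardized matrix.  Eigenvector signs are fixed by orienting
each loading vector so its largest-magnitude element is positive.  With
n years and q > n variables at most n − 1 components carry variance
(7 years × 19 variables ⇒ exactly 6), and the reported variance fractions
sum to 1.  A least-squares linear trend per series is provided for
summary tables; smoothed trend curves are a visualization concern and out
of scope.

## Synthetic data: what it emulates and what it does not

The track simulator moves each bird between a breeding centre (48.28°N)
and a wintering centre (29.1°N) through an ordered list of staging sites,
by great-circle interpolation at a constant 60 km/h ground speed, with
planned dwell times at each site (defaults: a long Luan-type staging bout
of 14 d southbound / 20 d northbound, a brief bay stop of 1 d / 3 d, and
a 2 d / 2 d river-basin stop), southbound departures drawn uniformly over
mid-September–mid-October and northbound departures over late
February–late March.  Fixes fall on a regular grid (default 2 h) plus an
anchor fix at every itinerary instant, making intervals irregular and the
planned dwells exact in the noise-free stream.  Position noise is
Gaussian; a configurable fraction of fixes emulate low-quality Argos
positions with location error drawn Uniform(100, 5000) m (and matching
position noise), the rest Uniform(0, 50) m, so the 100-m filter is
exercised deterministically.  Ground truth (event dates derived from the
noise-free stream at generation resolution, and every planned site visit)
is returned with the data.

The capture-history simulator applies the same age rule as the model and
marks configurable cohort sizes per year; its defaults are the real
program's scale (282 juveniles and 36 adults over seven cohorts,
2013–2019 with occasions through 2020), juvenile survival 0.76, adult
0.84, and a resighting rate rising linearly 0.29 → 0.78.  The nest
simulator draws covariates from Normal(mean, sd) per territory-year and
binary outcomes from a logistic model of the scaled covariates; default
effects encode water as the dominant positive driver of occupancy and
hatching, greenness positive, and heat and herder pressure negative, at
moderate effect sizes (|β| 0.4–0.8 on the scaled logit scale).  The
environment simulator produces linear-trend-plus-noise series (warming,
drying, shrinking surface water, growing human density).

None of this is behaviourally realistic: no wind, thermals, flocking,
route variability, tag failure, transience or trap response, and no
spatial covariate structure.  Passing recovery tests therefore shows that
the estimators are *correct under the stated models at realistic sample
sizes* — not that the models capture every feature of field data.

## Problem sizes and numerical choices

Recovery tests run at the study's scale where that is cheap (318
histories × 8 occasions, full 3 × 10,000 MCMC, 20 replicates; n = 5,000
nest records; 24 birds × 5 years of tracks) and at reduced scale where a
property does not need more (sampler determinism and degenerate-data
checks use a few hundred iterations).  Stopover recovery plants three
staging sites ≥ 3 days and > 50 km apart along a single-year route and
scores matches by individual, 25-km centroid proximity and a 1-day
arrival window.  IRLS convergence is max |Δdeviance| at 1e-8 within 100
iterations; PCA rank uses a relative eigenvalue tolerance of 1e-10;
cluster ties are measure-zero under continuous coordinates and are not
specially handled.

## Known limitations

- The CJS sampler is age × year only; the additive logit-scale age-offset
  variant is not implemented.
- Pooled site counts use two-stage (visit-centroid) pooling rather than
  clustering every stationary fix jointly; at single-digit-individual
  scale the two agree, at large scale joint clustering is quadratic in
  fixes and was deliberately avoided.
- Goodness-of-fit testing (e.g. median-ĉ) and multi-state extensions are
  out of scope, as are remote-sensing covariate extraction and map
  rendering.
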