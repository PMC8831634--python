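# Methods

This note documents the models and procedures implemented in `enmrisk`,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical decisions taken where the design was open.

## Occurrence cleaning

Records carry per-record status flags (`kept` / `dropped:<reason>`); no
record is ever deleted, so a cleaning report can account for every input.
The fixed order is: extent filter → invalid/duplicate removal → density
outliers → spatial thinning.

* **Extent.** Default box: latitudes 60°S–15°N, longitudes 90°W–30°W
  (eastern South America); boundary points are kept. The box guards
  against modelling truncated niches from records far outside the study
  region.
* **Validity.** Missing or non-numeric coordinates, |lat| > 90, |lon| >
  180, and (0, 0) — a common database artefact — are invalid; (0, 0)
  handling can be switched off. Exact coordinate duplicates collapse to a
  single kept record.
* **Density outliers.** A 2-D Gaussian KDE with per-axis Scott bandwidth
  (h_i = sd_i · n^(−1/6)) is evaluated at every kept record;
  the `floor(q·n)` lowest-density records are dropped (default q = 0.01),
  ties broken by record order. Because the rule is relative, re-applying
  it peels a further quantile: it is the one cleaning step that is not
  idempotent, and it is meaningful only for spatially clustered data.
  Fewer than 5 records: warn and skip.
* **Thinning.** Great-circle (haversine, R = 6371 km) distances; default
  minimum 20 km. Algorithm: repeatedly drop the record with the most
  conflicting neighbours, random seeded tie-break; then re-add any dropped
  record that no longer conflicts (maximality); repeat the whole procedure
  10 times on different tie-break draws and keep the largest retained set
  — the strategy of standard thinning tools. The result always satisfies
  the distance constraint and, in randomized trials, never retains fewer
  records than a greedy farthest-first packing.
* **Gate.** Species with fewer than 10 kept records are not modelled.

## Predictor screening

Variance inflation factors are computed from OLS of each variable on the
others (intercept included): VIF_j = 1/(1−R²_j), +inf under exact
collinearity. `vif_step` removes the largest-VIF variable until all are
below the threshold (default 5). Tie-break: the alphabetically later name
is removed, making the result independent of column order. VIF is
evaluated on background-cell samples (the modelled landscape), not at
presences. The per-growth-form candidate lists are shipped as editable
config; the default maps every growth form to all 19 bioclimatic
variables, since a priori ecological subsets are study-specific.

## Suitability model

A Gibbs (maximum-entropy) distribution over background cells,
p_raw(x) ∝ exp(λ·f(x)), with features f = (z_1..z_d, z_1²..z_d²) on
min-max-scaled predictors. Scaling bounds come from the background
sample; projections outside the bounds are clamped to [0, 1], so
quadratic terms cannot extrapolate unboundedly into novel climates.

The fit maximises the penalised presence log-likelihood
`mean_pres(λ·f) − log Σ_bg exp(λ·f) − Σ_j β_j |λ_j|` with
β_j = r · s_j/√m (r the regularisation multiplier, default 1; s_j the
feature sd over the m presences, floored at 1e-6). The problem is convex;
it is solved by L-BFGS-B on the split λ = u − v, u, v ≥ 0 (the L1 term
becomes linear), gradient tolerance 1e-5, at most 500 iterations. The
objective trace is recorded; it is non-increasing at every accepted
iterate. One caveat worth knowing: with this β, presence-mean sampling
noise is the same order as the penalty, and its excess is amplified by
the inverse feature curvature, so a no-niche fit can carry weights up to
|λ| ≈ 0.3 while the fitted distribution remains essentially uniform
(KL from uniform < 0.01) — weights, not suitability maps, are the noisy
quantity.

Output is the complementary log-log transform
`1 − exp(−e^H · p_raw)` with H the entropy of the fitted background
distribution; a completely uninformative model scores 1 − 1/e ≈ 0.632
everywhere. AUC is the rank-based (Mann–Whitney) statistic of presence vs
background scores, ties counting one half; it is a *training* AUC — the
significance control below, not a held-out split, guards against
optimism.

Bootstrap ensemble: each replicate (default 100) resamples the presences
with replacement; one background sample (default 10,000 cells, uniform
without replacement, capped at availability) is shared across replicates,
stabilising AUC comparisons. The ensemble map is the cell-wise mean of
replicate cloglog maps.

Response curves use the evaluation-strip idea: one predictor sweeps its
background range while the others sit at fixed reference values (default
mid-range; background means can be supplied).

## Null-model significance test

The null distribution is built by fitting the identical model
configuration to n cells drawn uniformly without replacement, 100 times,
and recording the training AUCs. A species' model is significant only if
its observed AUC strictly exceeds the empirical 95th percentile (linear
interpolation); the empirical p-value is (1 + #{null ≥ obs})/(n_null+1).
The distribution depends only on the landscape and n, so it is cached and
shared across species with the same record count. A pool argument allows
bias-corrected null sampling when a collection-effort surface is
available. Because the critical value is itself estimated from 100 null
fits and shared, rejection counts across many species are slightly
overdispersed relative to binomial — visible as seed-to-seed variation of
the type-I rate around 5%.

## Range dynamics

* **maxSSS threshold.** Candidates are the observed scores; sensitivity
  counts presences ≥ t, specificity counts background < t; the smallest
  candidate attaining the maximal sum wins. Applied once per species to
  the bootstrap-mean current map, then reused for all future consensus
  maps, so current and future binaries are comparable.
* **Consensus before binarisation.** Future members are averaged on the
  suitability scale and the mean is thresholded. Binarising members and
  majority-voting is a different (non-equivalent) estimator and is
  deliberately not the default.
* **BAH.** Minimum convex polygon of the kept records, buffered by 100 km
  in a Lambert azimuthal equal-area projection centred on the records'
  centroid (spherical earth, R = 6371 km); degenerate record sets buffer
  to capsules/discs. Cells belong to the BAH iff their centre falls
  inside the buffered polygon (boundary included); no partial-cell
  weighting.
* **Dispersal rules.** Non-dispersal: future occupancy = future ∩
  current (gains impossible; change ≤ 0). Full dispersal: any
  future-suitable cell inside the BAH. An alternative non-dispersal rule
  (`clip-mcp`: future suitability clipped to the unbuffered MCP) is
  available behind a flag, since published per-species tables
  occasionally show tiny non-dispersal gains that the literal
  intersection rule cannot produce.
* Change is 100 · (future − current)/current suitable-cell counts; loss
  and gain maps stack per-cell species counts of (suitable now, not in
  future) and the converse.

## Red List categorisation

* **Criterion B.** EOO = MCP area (same equal-area projection), floored
  at the AOO per IUCN guidance; AOO = occupied 2×2 km fixed-origin cells
  × 4 km². Thresholds: EOO < 100/5,000/20,000 km², AOO < 10/500/2,000 km²
  for CR/EN/VU; the more severe of B1/B2 applies. The accompanying
  conditions (fragmentation, continuing decline, extreme fluctuation) are
  not computable from coordinates; the caller supplies how many are met
  (default 2, the minimum for a non-advisory category), and all output is
  labelled preliminary.
* **Criterion A3c.** Projected habitat loss ≥ 30% → VU, ≥ 50% → EN,
  ≥ 80% → CR; gains are never threatened. The mapping is monotone by
  construction.
* **Summaries.** Per scenario/period/dispersal column: category counts
  and percentages over the full species count, the mean decline under two
  conventions (mean of −change over all species; mean loss over declining
  species only — published "average declines" do not state which), the
  maximum increase, and the count of species losing 100% of habitat.
  Percentages are *floored* to one decimal: the published study's printed
  fractions are floor-rounded (e.g. 93/135 = 68.888… printed as 68.8,
  48/135 = 35.55… printed as 35.5), and this package follows that
  convention. The packaged table (`data/table1_fixture.csv`, 135 species
  × 8 columns with use groups) is guarded by a SHA-256 checksum. Note
  that the source study's own figure-level summaries for the
  SSP5-8.5/2061–2080 columns are mutually inconsistent with its printed
  per-species table (its text also cites one species as 263% where its
  table prints 264.0); this package reports what the table arithmetic
  gives.

## Synthetic data

Climate layers are Gaussian random fields (white noise smoothed with a
Gaussian kernel of radius `autocorr_range` cells, default 5), standardised
to zero mean/unit variance over valid cells — capturing the spatial
autocorrelation of real bioclimatic surfaces but none of their physics,
cross-variable structure, coastlines or gradients. Virtual species use
the same cloglog response family as the model, η = Σ a_k z_k + b_k z_k²,
so parameter recovery is well-posed. Presence-only sampling draws cells
∝ suitability × optional bias, jitters coordinates uniformly within the
cell, plants `round(n·f_out)` uniform outliers and `round(n·f_dup)` exact
duplicates. Future "GCM members" are the current stack plus per-layer
mean shifts plus member-specific smooth noise (rescaled to a marginal sd
= `noise_scale`); the member mean converges to current+shift at the 1/√G
rate. Every generator is a pure function of its inputs and seed.

Two structural consequences of the cloglog family matter for what the
tests can show. First, η = 0 maps to suitability 0.632, so cells at a
predictor's minimum are never fully unsuitable; genuinely selective test
species need either strong negative curvature or a band niche in two or
more variables (single-variable niches have landscape-dependent realized
selectivity because min-max scaling tracks the field extremes). Second,
convex niches (b > 0) have η ≥ 0 everywhere, capping their sampling
contrast at (1−1/e)⁻¹ ≈ 1.6:1 — their curvature sign is statistically
unrecoverable, so quadratic-sign recovery is validated on bell-shaped
(b ≤ −2) niches, the canonical unimodal climate response.

Passing tests on these data demonstrate correctness of the machinery and
its statistical calibration under known truth; they do not validate
niche-model transferability, the equilibrium assumption, sampling-bias
correction on real collections, or real GCM uncertainty structure.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 40×40 and 50×50
grids, 800–2,000 background cells, 8 bootstrap replicates, 100 null
repetitions, and 20–200 simulation repetitions per property — sizes at
which every statistical property examined is already stable and the
whole suite runs in seconds. Degenerate inputs fail loudly: empty
predictor lists, constant predictors over background, zero suitability,
empty current ranges and sub-minimum record sets all raise. The cloglog
double exponent is clipped at ±700 before exponentiation (beyond which
the output saturates in float64 anyway). Quantiles are linear-interpolated
(type 7) throughout.

## Known limitations

* Criterion B conditions (a)–(c) are inputs, not inferences; categories
  are preliminary by design.
* The non-dispersal intersection rule cannot produce gains; the `clip-mcp`
  alternative only partially explains small published non-dispersal gains.
* Background sampling is uniform over the landscape; the bias-grid hook
  exists but no bias-correction surface is generated synthetically.
* Feature space is restricted to linear + quadratic terms; hinge/product/
  threshold features of the original MaxEnt tool are out of scope.
* Raster I/O is plain-text ESRI ASCII grids — adequate for the grid sizes
  here, not for continental 5-arc-minute stacks.
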