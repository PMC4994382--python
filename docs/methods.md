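# Methods

This note documents the statistical machinery behind `prevmap`: the three
estimation methods, the synthetic survey generator that serves as their
test bed, the numerical choices, and the limits of what the test suite
demonstrates.

## Data model

The pipeline operates on a respondent table (one row per woman aged 20–29:
cluster id, positive survey weight, age, age-at-first-birth band), a
cluster table (published displaced GPS point, urban flag, district id),
and nested admin polygons (level 1 regions containing level 2 districts)
in WGS84 lon/lat. The outcome is categorical with four codes: first birth
before 16 (`LT16`), at 16–17 (`A16_17`), at 18–19 (`A18_19`), or none
before 20 (`NONE_BEFORE_20`, the baseline — it pools women whose first
birth came at 20+ with never-mothers, because the estimand is "share of
women with a first birth before age x", a population proportion).

A respondent's district is the one recorded on her cluster, never derived
by point-in-polygon on published coordinates: published cluster points are
displaced for confidentiality (uniformly random direction, distance
uniform on [0, 2 km] urban / [0, 5 km] rural), so spatial assignment near
borders misclassifies. `assign_districts_by_point` exists for data lacking
the field, with that caveat documented on the function.

## Survey-weighted prevalence

For group g and band k, `p̂ = Σ_{i∈g} w_i 1[band_i = k] / Σ_{i∈g} w_i`.
Properties relied on downstream: invariance to rescaling all weights;
pooled estimates are weight-proportional convex combinations of group
estimates; groups with zero denominator are *missing*, not zero. With unit
weights the estimator reduces to the plain proportion, which is how the
bundled published count table (9,798 respondents over three countries)
pins it to known one-decimal percentages. Conditional breakdowns (e.g.
no-education share among women with first birth <16) restrict the
denominator to the band. No design-based variance is attached to weighted
estimates; an unweighted Wilson interval is available for diagnostics
only, since it ignores weighting and cluster sampling.

## Adaptive-bandwidth kernel prevalence surfaces

Per-cluster bandwidths follow a nearest-neighbour rule: h_i is the
great-circle distance at which the cumulative respondent count (cluster i
itself plus every cluster within h_i) first reaches `N_opt`. Edge rules:
a cluster already holding `N_opt` takes its nearest-other-cluster distance
(a strictly positive floor); a total sample below `N_opt` falls back to
the farthest-cluster distance with a warning; coincident clusters are
floored at 1 m. `N_opt` is the main tunable — about 500 persons for a
full national survey; for smaller synthetic runs the default is
`max(5 × mean cluster size, total/20)`, which keeps roughly the same
clusters-per-kernel ratio.

The density at a cell is `Σ_i value_i · w_i · K(d_i/h_i) / h_i²` with K
the bivariate Gaussian kernel (1/2π · exp(−t²/2)) and d great-circle
distance. The prevalence surface is the cellwise ratio of the case
density (values = per-cluster band events y_i) to the control density
(values = respondent counts n_i), with *identical* bandwidths and weights
on both sides. That sharing is what makes the ratio a prevalence: every
cell is a convex combination of cluster prevalences y_i/n_i, so a
constant-prevalence field reproduces the constant to machine precision —
the module's sharpest test — and surface values never leave the range of
cluster prevalences. The Gaussian kernel was chosen over a truncated ring
because its infinite support makes the constant-field identity exact
everywhere; a truncated quartic kernel is available (`kernel="quartic"`)
for sensitivity checks.

Cells whose control density falls below a support floor are masked
no-data rather than reporting a ratio extrapolated from kernel tails; the
default floor is the density one respondent contributes at twice the
median bandwidth. Kernels are weighted by survey weights by default
(unweighted mode available). Published (displaced) coordinates are used
as-is: at bandwidths of tens of km the ≤5 km displacement is absorbed by
the smoothing and no correction is attempted. Rasters are exported as
Esri ASCII grids (cell size in degrees of latitude; the plate-carrée
format cannot express the cos-latitude east–west scaling, noted in the
writer's docstring) plus a lon/lat/value CSV of supported cells.

## Small-area model

Per band and country-analogue, the binomial logit BYM model of the README
is fit on district counts (y_d, n_d) from `outcome_counts`, which keeps
zero-trial districts so they are *predicted*, not dropped. The contiguity
graph uses queen adjacency (any shared boundary point). Islands would
leave the ICAR prior uninformative, so the default policy joins each
island to its nearest unit by centroid distance; a strict mode leaves
them disconnected (they then rely on the exchangeable effect and the
intercept alone, surfacing as wide intervals).

Sampling is Metropolis-within-Gibbs:

- τ_u | u ~ Gamma(a_u + rank(Q)/2, b_u + ½·Σ_{i~j}(u_i−u_j)²), with
  rank(Q) = n − #components computed combinatorially, not numerically;
  τ_v | v ~ Gamma(a_v + n/2, b_v + ½Σv²).
- β₀, each u_d, each v_d: random-walk Metropolis on the logit scale. The
  structured field is updated in graph-colour classes — within a class no
  two districts are neighbours, so the single-site conditionals are
  mutually independent and a whole class is proposed and accepted
  elementwise in one vectorised step (2 classes on a rook lattice, ~4
  with queen moves). The exchangeable field updates all sites at once the
  same way.
- After each sweep the mean of u is moved into β₀ (u ← u − ū,
  β₀ ← β₀ + ū), enforcing the sum-to-zero constraint without changing the
  likelihood.
- Proposal scales adapt every 50 iterations of burn-in toward ~35%
  acceptance (inside the 20–50% band that keeps random-walk samplers
  efficient) and are frozen afterwards so the post-burn-in chain satisfies
  detailed balance.

Default priors — β₀ ~ N(0, 10²), τ_u, τ_v ~ Gamma(1, 0.01) — are the
weakly informative choices common for this model class; all are config
keys, so prior sensitivity is explored by configuration rather than code
changes. The core model is intercept-only; district-level linear
covariates with N(0, 10²) coefficient priors can be added through
`ModelSpec.covariates`.

Summaries report, per district, the posterior mean of p_d (the mean of
the inverse-logit-transformed draws — transforming the mean would be
biased on a skewed posterior), SD, empirical 2.5%/97.5% quantiles, and
effective sample size via the autocorrelation-time estimator. Defaults of
6,000 iterations (2,000 burn-in, thin 2) give ESS in the hundreds per
district on lattices of a few dozen districts.

The model posterior is the contract here: MCMC was chosen over a nested
Laplace approximation because at these problem sizes a well-mixing chain
reaches the same posterior while remaining a few hundred lines of
auditable numpy; this is the package's one deliberate methodological
substitution relative to common practice in the small-area literature.

## Synthetic survey generator

The generator emulates the structure of an East-African DHS-style survey:

- **Admin lattice** — rectangular district cells (default 50 km edge)
  tiled into contiguous near-square region blocks; 8 regions × 5
  districts by default. Cell edges are drawn from shared coordinate
  arrays so neighbouring polygons touch exactly (no floating-point
  hairline gaps).
- **Outcome model** — multinomial logit over the four codes with baseline
  "no birth before 20": p_dk ∝ exp(β₀k + u_dk + v_dk). Each band gets its
  own ICAR-distributed structured field (u ~ N(0, σ_u²·Q⁺), drawn by
  eigendecomposition of the graph Laplacian, sum-to-zero by construction)
  and i.i.d. normal field. The marginal model for any single band is
  exactly the binomial BYM model the fitting stage assumes, so parameter
  recovery is a fair test. Default intercepts give pooled prevalences of
  roughly 10/20/25%, the magnitudes seen in the region's surveys; default
  σ_u = 0.3, σ_v = 0.15 put most districts within ±2 σ ≈ ±0.67 logits of
  the country mean — visible spatial structure without degenerate
  probabilities.
- **Scale** — Poisson(10.5) clusters per district and Poisson(8,
  truncated ≥1) women per cluster give ≈420 clusters and ≈3,300
  respondents, matching the single-survey scale the pipeline targets.
  Zero-cluster districts are retained to exercise the unobserved-district
  path.
- **Displacement** — uniform angle, uniform distance within 2 km urban /
  5 km rural, in a local flat-earth frame (km-per-degree with
  cos-latitude scaling; sub-metre error at these distances near the
  equator). The rarer long-range rural displacement some survey programs
  apply to a 1% subsample is deliberately not modelled, and displacement
  is not constrained to stay within the source district — membership
  travels as an explicit field, with an opt-in flag to reassign from
  displaced points so misclassification can be quantified.
- **Weights** — lognormal, mean-normalised, CV 0.3 by default. Real
  survey weights encode design and non-response adjustments the generator
  does not attempt; downstream code accepts any positive weights.

What passing tests on this generator do *not* show: robustness to real
DHS two-stage sampling, stratification and non-response weighting, to
non-convex district geometries, or to outcome misreporting (recall bias
on age at first birth). Those are properties of real data the generator
intentionally does not emulate.

## Numerical and design choices

- Distances: haversine on a sphere of radius 6371.0088 km; local
  flat-earth projection only for generating offsets and polygon areas at
  ≤50 km scale.
- Grids: row-major from the north-west corner; default 5 km cells for
  surfaces (10 km in examples to keep them instant).
- Determinism: every stochastic routine takes a seed or Generator; the
  pipeline derives stage seeds from one config seed by stable hashing, so
  stages rerun independently yet reproducibly, and a run manifest records
  the config hash and versions.
- Degenerate inputs: a single cluster below `N_opt` yields a warned
  floor bandwidth; a constant posterior chain reports SD 0 with a
  warning; empty respondent sets, non-positive weights, y > n, dangling
  foreign keys and invalid geometries raise typed errors naming the
  offenders.
- Test problem sizes: the calibration suite uses a 6×6 lattice with
  n_d = 100 over 20 replicates (720 district-truths) and 4,000-iteration
  chains, sizes at which interval coverage stabilises near its nominal
  level while the suite stays quick to run; the single-district
  quadrature check uses 50,000 retained draws.

## Known limitations

- The ICAR variance parameter is interpreted as the marginal SD under the
  Laplacian pseudo-inverse covariance; other conventions (conditional
  variance) rescale σ_u by the typical neighbour count.
- The KDE stage reports no uncertainty; it is an exploratory smoother.
  Formal interval estimates come from the model stage.
- Queen contiguity on heavily multi-part real-world polygons can produce
  spurious corner adjacencies; rook adjacency is available for lattices
  (`grid_adjacency(..., rook=True)`) but not derived from polygons.
- The sampler is single-chain; ESS and the acceptance-rate log are the
  mixing diagnostics. For publication-grade runs, fit with several seeds
  and compare summaries.
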