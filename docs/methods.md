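# Methods

## The question the pipeline answers

When a population meets an environment it has not adapted to, three
multivariate quantities decide whether rapid adaptation is possible: the
additive genetic (co)variance matrix **G** of the relevant traits in that
environment, the direction of phenotypic plasticity between environments,
and the direction of selection. `gmatpipe` estimates per-environment
**G**-matrices from a paternal half-sib breeding design, quantifies how
**G** changes across environments (genotype-by-environment interaction,
G × E), and measures how much of the available genetic variance lies along
the plasticity, selection, and between-species phenotype directions.

## Quantitative-genetic model

For one species in one environment, offspring trait vectors (p traits,
mean standardized) follow

```
y_ijkl = mu + s_i + d_j(i) + b_k + e_ijkl
```

with multivariate-normal random effects: sire `s ~ N(0, Sigma_sire)`,
dam-within-sire `d ~ N(0, Sigma_dam)`, experimental planting block
`b ~ N(0, Sigma_block)` and residual `e ~ N(0, Sigma_resid)`. All four
components are full p × p covariance matrices estimated jointly. Under the
half-sib interpretation the sire component estimates one quarter of the
additive genetic (co)variance; the sire matrix itself is reported as **G**
(`scale=1` default), with the × 4 additive scale one flag away. All
*proportional* downstream quantities (eigen-proportions, angles,
projection ratios) are identical under either scale.

Two block concepts must not be conflated. The *breeding block* (3 sires
× 3 dams mated full-factorially) structures the pedigree only. The
*planting block* is the field randomization unit, crossed with families —
every family's seeds are spread over every block of a site. The model's
`b_k` is the planting block. Treating the breeding block as the model's
block term makes the sire variance unidentifiable from between-block
variation (we verified the sire component is then absorbed into the block
component), so the data schema carries the planting block.

Dam-within-sire levels are the full-sib families (sire × dam
combinations). The full-factorial crossing could also support a sire × dam
interaction component; it is deliberately pooled into the residual, which
costs nothing for **G** and improves identifiability.

## Sampler and priors

The model is fit by Gibbs sampling with conditionally conjugate updates:
batched multivariate-normal draws for all effect vectors of a term
(grouped by replicate count so balanced designs reduce to a single stacked
Cholesky), a flat-prior normal draw for the grand mean, and
inverse-Wishart draws for the covariance components. Inverse-Wishart
variates use the Bartlett construction directly (agreement with
`scipy.stats.invwishart` is unit-tested); the generic scipy interface is
too slow for the millions of draws the permutation tests require.

Each random term uses **scalar parameter expansion**: the effect is
written `alpha_t * u` with `u ~ N(0, W_t)`, `W_t ~ IW(p + 1, I)` and a
near-flat normal prior on the working scalar `alpha_t` (sd 100 by
default); the reported component is `alpha_t^2 W_t`. Without expansion,
plain Gibbs both mixes slowly (the classic scale trade-off between a
variance component and its effects) and shrinks small components toward
the prior scale: on simulated designs the sire posterior mean sat ~20%
below the closed-form ANOVA estimator and 95% HPD coverage of true G
elements was only 0.85. With expansion the posterior mean tracks the ANOVA
oracle within a few percent and coverage is ~0.98. The residual component
keeps a conventional `IW(p + 1, 0.5 * vbar * I)` prior (`vbar` = mean
observed trait variance); all hyperparameters are configurable through
`MixedModelSpec`.

Chain defaults are desk scale (burn-in 5,000, thin 10, 1,000 saved draws);
journal-scale settings (burn-in 150,000, thin 1,500, 2,000 draws) are a
configuration away. `diagnose_chain` reports per-element lag-1
autocorrelation (pass threshold 0.05) and effective sample size via arviz.
Autocorrelation is intrinsic to the design — only three dams inform each
sire's mean — which is why heavy thinning is conventional for these
models.

## Mean standardization

Each trait is divided by a reference mean, so variances become
mean-standardized variances (evolvabilities) and traits measured in
different units are comparable. The default reference is the per-species
grand mean pooled across environments: per-context standardization would
force every standardized context mean to 1 and erase the plasticity
vectors. Per-context and user-supplied references are available.
Standardization commutes with group means (tested).

## Comparing G across contexts

* **Eigenanalysis**: descending eigenvalues, unit eigenvectors with the
  largest-|loading| entry made positive (a deterministic sign convention;
  eigenvector signs are otherwise arbitrary).
* **Angles**: `theta = arccos(|r|) * 180 / pi` with `r` the vector
  correlation; in [0°, 90°] and invariant to sign flips. Posterior angle
  distributions pair draws by index (chains are independent, so index
  pairing is arbitrary but harmless).
* **Covariance tensor**: each G is vectorized with √2-weighted
  off-diagonals (making vectorization an isometry for the Frobenius inner
  product); the S-matrix is the sample covariance (denominator m − 1) of
  the m vectorized matrices; its eigenvectors are rearranged into
  symmetric eigentensors. With m contexts at most m − 1 eigenvalues are
  nonzero. When posteriors are supplied, S is computed per paired
  posterior draw and averaged; eigentensors come from the averaged S, and
  coordinates (Frobenius inner products ⟨G_i, E_k⟩) are recorded per draw,
  so coordinate posteriors can be summarized like any other. The variance
  of coordinates across the inputs equals the corresponding S eigenvalue
  exactly — an identity the tests verify to 1e-8.

## Randomization nulls

Variance components are constrained positive, so "is this G element
real?" is answered against a randomization null rather than against zero.

* **Element-wise null for G** (`null_G_test`): refit after destroying the
  sire signal, compare the observed posterior mean with the null
  distribution of posterior means; one-sided exceedance at the (1 − α)
  quantile, off-diagonals compared on absolute value. The default
  randomization reassigns *intact families* to sires: this destroys
  exactly the sire-level grouping while preserving the family (dam)
  variance layer, and calibrates correctly (~1–5% false-positive rate at
  α = 0.05 in our Monte Carlo). Shuffling individual offspring among
  families (also provided, `unit="offspring"`) additionally dissolves the
  family layer; null refits then see less upper-level noise than the
  observed data and the test runs anticonservative (~14% in the same
  Monte Carlo). Neither scheme moves rows between planting blocks, so
  block differences are preserved.
* **Tensor null** (`null_tensor`): a shared-G breeding-value
  randomization. Per replicate and context, sire effects are replaced by
  fresh draws from `N(0, G_common)` — `G_common` the across-context mean
  of the fitted sire matrices — on top of the retained dam/block/residual
  layers (`y* = y − ŝ + s_sim`); the model is refit at reduced settings
  and the tensor recomputed; observed eigentensor eigenvalues are flagged
  when they exceed the (1 − α) null quantile. This simulates changes in G
  due to sampling alone. Fresh draws are used instead of permuting the
  predicted effects because posterior-mean effects are shrunk: redealing
  them between contexts underdisperses the null (in our Monte Carlo the
  permutation variant flagged sampling-only differences in 3 of 4 H0
  replicates, while the shared-G simulation flags at the nominal rate and
  retains full power for a five-fold sire-variance difference).

## Directions and projections

* Plasticity: `Δx̄ = x̄_native − x̄_other` on mean-standardized traits.
* Native phenotype: between-species mean difference at one environment.
* Selection: multiple logistic regression of survival on all traits
  jointly (the joint fit supplies the phenotypic-covariance adjustment of
  the classical `β = P⁻¹ s`). Logit coefficients are moved to the
  probability scale by the average-gradient transform (× mean of
  p̂(1 − p̂); the evaluate-at-mean-survival alternative is a flag) and to
  the relative-fitness scale (÷ mean survival). The three scales are
  positive multiples of one another, so the unit direction is shared.
  Gradients are only estimated where enough post-measurement mortality
  exists (default refusal below 5% deaths among measured individuals) —
  without deaths after measurement there is no fitness variation to
  regress on. Uncertainty comes from a case-resampling bootstrap;
  family-mean ("genotypic") gradients use a binomial GLM on family
  survival fractions weighted by family size.
* Projection: for unit v and a G draw, `(vᵀ G v) / λ_max` with λ_max the
  leading eigenvalue of the same draw — the proportion of the maximum
  genetic variance available that lies along v, in [0, 1], equal to
  λ_k/λ_max when v is the k-th eigenvector. Vectors are always normalized
  first: without normalization the ratio is not bounded by 1 and the
  "proportion of the maximum available" interpretation fails. Posterior
  propagation pairs each vector draw with one randomly chosen G draw by
  default (full cross products and index pairing are options); two
  projection distributions are called credibly different when their 90%
  HPD intervals do not overlap.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes:
full-factorial 3 × 3 sire-by-dam breeding blocks (12–13 per species, the
last block optionally smaller), ~25 offspring per family per environment
across four environments, per-environment sire covariances (G × E),
shared dam effects, planting-block effects (5 blocks per environment,
crossed with family), environment-specific trait means (plasticity),
logistic trait-dependent survival, random family dropout (failed crosses)
and random pre-measurement mortality. Sire effects across environments
are built as `u_a = L_a(√ρ z0 + √(1−ρ) z_a)` with `L_a` the environment's
sire-covariance factor, giving exact per-environment marginals and a
cross-environment genetic correlation `rho_GE` (default 0.5 — a free knob,
not an estimate; no field value exists for it). All randomness derives
from one master seed through deterministically spawned sub-streams, so
identical seeds give bit-identical tables.

The bundled two-species configuration (`study_config`) puts trait means
near 1 (the mean-standardized scale) with sire variances of a few
percent, stronger G × E for the high-elevation species at novel low
elevations, and milder G × E for the low-elevation species — the two
qualitative regimes the projection analysis distinguishes. Pre-measurement
mortality defaults to random with respect to phenotype (the
trait-dependent option exists to study the bias it would cause);
family dropout defaults approximate realized cross-failure rates
(0.13 / 0.04).

What the simulation does *not* emulate: germination phenology, spatial
arrangement within blocks, non-Gaussian trait distributions, selection
acting before measurement by default, and fecundity selection. Passing
tests therefore demonstrate that the estimation and comparison machinery
recovers known structure from data obeying the model's assumptions — not
that field data obey them.

## Scenario fixtures

`scenario_config` builds two-trait, two-environment caricatures of the
interesting regimes: `aligned` (no G × E), `gxe_gain` (the novel
environment's G reorients toward the direction of selection) and
`gxe_loss` (variance along selection collapses at the novel environment —
the constraint case). The sire-variance contrasts are strong (roughly a
five-fold swap between the two traits) so that the qualitative ordering
of projections is a property of the construction, not of sampling luck,
at a 12-block desk-scale design.

## Problem sizes and numerical choices

The test suite runs the expensive checks at deliberately reduced scale,
chosen as the smallest designs at which the statistical property under
test is decisively expressed: parameter recovery at 36 sires × 3 dams ×
15 offspring with 5 traits (20 replicates; burn-in 1,000 / thin 8 / 500
draws), null calibration at 12 sires × 2 traits with 50 permutations per
replicate and short chains, and the scenario ordering at 12 blocks × 10
offspring with 2 traits. Degenerate inputs are handled explicitly:
zero-variance generators produce exact constants (PSD factors via
eigendecomposition, not jittered Cholesky); zero direction vectors are
flagged degenerate and refuse normalization; G draws with zero leading
eigenvalue refuse projection. Posterior HPDs use `arviz.hdi` throughout.

## Known limitations

* The sampler covers the two-level sire/dam nesting plus crossed blocks —
  it is not a general animal model and takes no pedigree inverse.
* Randomization nulls and tensor nulls at paper scale (1,000 permutations,
  journal-length chains) are hours of CPU; defaults are desk scale.
* The family-reassignment null assumes sires are exchangeable across
  breeding blocks under H0; with strong block-confounded maternal
  structure the offspring-level scheme within blocks may be preferred
  despite its conservatism trade-off.
* HPD-overlap screening is a heuristic comparison, not a formal test of
  distributional difference.
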