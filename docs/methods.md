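# Methods

This note documents the models, numerical choices and known limitations of
`cladediv`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The question and the unit of analysis

The package compares *clades* — independent monophyletic sets of
populations, usually species, sometimes monophyletic halves of a
paraphyletic species — and asks which clade-level properties predict the
clade's average genetic divergence among its populations. Candidate
predictors are clade age (older lineages have had more time to diverge),
environmental heterogeneity within the range (isolation by environment),
and ecomorph class (a proxy for dispersal-relevant morphology and
microhabitat); mean geographic distance among the sampled localities enters
as a covariate because sampling designs that span larger ranges mechanically
produce larger divergences (isolation by distance).

## Response: average between-locality divergence

Divergence is measured on a population phylogeny with branch lengths in
substitutions/site. For a clade sampled at localities *p, q, …*, the
distance between two localities is the mean patristic distance over all
cross-locality sample pairs; the clade's divergence is the unweighted mean
over unordered locality pairs. Two deliberate choices:

* **Within-locality pairs are excluded.** Divergence is an among-population
  quantity; within-locality variation is nuisance.
* **Locality pairs are weighted equally**, not by sample count, so a heavily
  sampled locality does not dominate. `weighting="sample-pairs"` switches to
  sample-pair weighting when sample sizes are meaningful.

Clade curation is data-driven (`CladeRules`): species splits by locality
sets, per-sample exclusions (e.g. putative hybrids) with mandatory reasons,
clade exclusions, and an automatic flag for clades left with fewer than
`min_localities` (default 3) sampled localities — too few pairs to estimate
an average divergence.

Species-level genetic distances for the covariance construction can be
computed from aligned sequences under p, JC69 or K2P models. Columns with
gaps/ambiguity are removed alignment-wide by default (`deletion="complete"`);
per-pair removal is available. Any monotone distance serves the covariance
construction, so the model choice is a recorded configuration field rather
than a scientific commitment.

## Covariates

* **Geographic distance**: haversine on a sphere of radius 6371.0088 km.
  At the few-hundred-km scales of an island study the difference from an
  ellipsoidal geodesic is < 0.5% and cannot affect rank-based conclusions;
  the radius is a constant, not a fitted quantity.
* **Environmental heterogeneity**: the 20 locality variables are normalized
  by PCA on the correlation matrix — centering plus unit-variance scaling —
  because bioclim-style variables mix units (0.1 °C vs mm) and a covariance
  PCA would be dominated by precipitation. One PCA is fitted over *all*
  localities jointly; per-clade heterogeneity is the mean Euclidean distance
  between the clade's localities on axes 1–5. K = 5 is a configuration
  field; axis signs follow the convention that each axis's
  largest-magnitude loading is positive, making outputs reproducible across
  linear-algebra backends. A covariance-matrix PCA is available via
  `use_correlation=False`. `grid_average` coarsens point values onto a
  square grid (default 5 km) to emulate working at a raster resolution that
  covers a population's whole habitat.
* **Age**: read off an ultrametric chronogram (tip-depth spread must be
  ≤ 1e-6 of depth). Default is **stem age** — the height of the parent of
  the clade's MRCA — because it exists for single-population clades and is
  the age of origin of the lineage; crown age is available by flag, and
  crown age of a single-tip clade falls back to stem age with a warning.
  Each clade must be monophyletic in the chronogram; violations are reported
  with the intruding tips.

## PGLS engine

Under Brownian motion, trait covariance between clades is proportional to
shared root-to-divergence path length. Two routes to **C**:

* from an ultrametric tree: `C_ij` = depth of the MRCA of *i* and *j*;
* from a pairwise distance matrix: UPGMA ultrametrization (average linkage,
  merge height d/2; ties broken by the lexicographically smallest pair of
  cluster labels, so the result is deterministic), then with cophenetic
  distances `u` and depth `T = max(u)/2`, `C_ij = T − u_ij/2`, `C_ii = T`.

The fit whitens through the Cholesky factor of the correlation-scaled
`C* = C/T` (a jitter of 1e-10 on the diagonal is added, and logged, only if
the factorization fails). The residual variance is profiled out by **ML,
not REML**, because backward elimination compares fixed-effect structures by
likelihood ratios and REML likelihoods are not comparable across different
design matrices. The profiled log-likelihood is

```
ℓ = −(n/2)·ln(2π σ̂²) − ½·ln|C*| − n/2,   σ̂² = RSS_GLS / n,
```

which is invariant to any overall rescaling of C (tested). Standard errors,
t and sequential F statistics use the df-corrected variance `RSS/(n−p)`, so
that with an identity covariance the output coincides exactly with OLS.
Sequential (type-I) F tests add terms in formula order; categorical terms
are dummy-coded against the alphabetically first level (changing the
reference changes coefficients but not F or the likelihood — tested).

**Backward stepwise.** At each step the droppable term with the largest LRT
p-value above α (default 0.05) is removed; interactions are always
droppable, a main effect only when no retained interaction contains it.
After convergence, a main effect that survives only because an interaction
holds it in place is removed unless it was itself significant in the full
model — "significant in the full model" is operationalized as the LRT
p-value of dropping that single term from the full model. The elimination
trace records every removal with its statistic, df, p and the rule that
fired.

**Degenerate fits.** With a noise-free response the GLS residual sum of
squares is machine noise and likelihood differences between two perfect fits
are meaningless; `lrt` detects mutually *saturated* fits
(RSS ≤ 1e-20 × TSS) and returns statistic 0, p 1, so an uninformative term
is dropped rather than producing an arbitrary log-ratio of rounding errors.

## Synthetic data generator

The generator emulates the study design, not sequence evolution:

* **Chronogram**: Yule (pure birth) with rate 0.1/lineage/Myr, node heights
  rescaled so the root is at 95 Myr. Extinction is omitted deliberately —
  it adds nothing testable about age effects at fixed n.
* **Geography**: a 1000-km square "island"; each of the (default 26) species
  occupies a random sub-box of 100–600 km and is sampled at 3–8 localities.
* **Environment**: each of the 20 variables mixes a unit-variance linear
  island-wide gradient with white noise; `env_autocorr` (default 0.7) is the
  gradient's variance share. Variables are then shifted to field-plausible
  means/sds (temperatures in 0.1 °C, precipitation in mm, tree cover in
  percent, clipped to [0, 100]).
* **Divergence**: `μ = β_age·age + β_geo·geodist + β_env·envhet` with
  defaults β_age = 0.0015/Myr, β_geo = 2e-5/km, β_env = 0. The residual is
  `√λ·b + √(1−λ)·e` with b a Brownian draw on the chronogram scaled to
  marginal sd `noise_sd` (default 0.005), e white with the same sd, and
  λ = 0.5 by default; values are truncated at 0 (a warning fires if more
  than half the clades go negative). Covariates are *measured with the real
  geodesy/environment/comparative modules*, not redrawn.
* **Population trees**: each species' divergence is realized as a star of
  locality subtrees with stem length divergence/2 (plus an optional
  within-locality branch, default 0), so every between-locality patristic
  distance equals the drawn divergence exactly and the measurement chain
  round-trips to 1e-9. Within-species topology is irrelevant to the
  analysis, which only uses between-locality averages.
* **Ecomorphs** are allocated in study-like proportions by largest-remainder
  quota and shuffled, so every sufficiently frequent class is present and
  dummy-coded designs stay full rank at realistic n. Body size is drawn
  around 145 mm for crown-giants and 50 mm otherwise.

Randomness: one integer seed; sub-streams are derived through fixed
`SeedSequence` offsets per purpose and per species, so runs are
bit-reproducible and adding a species does not perturb earlier species'
locality draws.

What the generator does **not** emulate: coalescent/migration structure
within species, sequence-level evolution, range shapes beyond boxes,
spatially structured sampling effort. Passing tests therefore demonstrate
correctness of the measurement and inference chain under the stated model,
not robustness to every feature of real data.

## Replicated studies (`cladediv.experiments`)

* **Parameter recovery** (200 replicates at the default design): each
  replicate simulates a dataset, re-measures divergence from the emitted
  trees, and fits `age + avg_geodist + env_het` by PGLS under the true
  chronogram covariance; reported are the age-effect estimates and whether
  the 95% Wald interval (t quantile, n−p df) covers the truth. Note that
  with λ = 0.5 the fitted pure-BM covariance is deliberately misspecified
  (Pagel-λ estimation is out of scope), which makes the standard error of
  the tree-structured age term conservative; interval coverage runs at or
  slightly above 0.99 rather than 0.95. Under λ = 1 (correctly specified)
  coverage is near-nominal.
* **Stepwise null calibration**: the null response is the raw Gaussian
  phylogenetic residual (λ = 1, no zero-truncation) so the study measures
  the *size* of the LRT elimination under the model it assumes rather than
  its robustness to the floor at zero divergence; candidate terms are the
  three continuous covariates. The χ²(1) reference for the LRT is known to
  be anticonservative at n = 26 (the equivalent exact-F size is ≈ 7%), so
  per-term retention runs somewhat above the nominal 5%.

Problem sizes (200 replicates, n = 26 clades, 3–8 localities each) keep each
study under a minute on one CPU while leaving Monte-Carlo error around one
percentage point on retention/coverage rates.

## Pipeline

`run_pipeline` materializes every intermediate as CSV (divergences, distance
matrices, PCA scores, ages, the assembled clade summary, model reports,
elimination trace, run metadata with a config hash that excludes paths so
identical runs into different directories produce identical files). Any
stage failure moves partial outputs to `quarantine/` and re-raises with the
stage name. `make_fixtures` writes a small worked dataset (8 clades,
3–4 localities each) plus its expected outputs for integration tests.

## Known limitations

* Covariance misspecification under mixed residuals is not corrected (no
  Pagel's λ or OU transform) — by design, see above.
* The zero-truncation of divergence makes the generative model non-Gaussian
  near zero; fits treat the response as Gaussian, as the analysis model
  does.
* UPGMA is the sole ultrametrization for distance-matrix covariances;
  alternatives (e.g. least-squares trees) are out of scope.
* Geographic distances are spherical; no least-cost or overwater paths.
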