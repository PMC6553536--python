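# Methods

This note documents the statistical models implemented in `structgs`, the
choices made in estimating them, and the scope of the synthetic-data
generator. Everything stated here is either a model definition or a property
verified by the test suite; no empirical claims are made beyond what the
package itself computes.

## Synthetic generator

`simulate_structured_genotypes` draws a panel of `n_subpops` diverged
populations under the Balding–Nichols model: an ancestral allele frequency
`p ~ Uniform(ancestral_maf_range)` per marker, population frequencies
`~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with `F = fst`, and dosages
`~ Binomial(2, freq)`. Consequences used by the tests: Hardy–Weinberg holds
within each population by construction; Hudson's FST estimator recovers `F`;
pooling populations produces a Wahlund heterozygote deficit that grows with
`F`. Markers are independent given population frequencies — there is no
linkage-disequilibrium structure along chromosomes, so `ld_decay` on
simulated data shows only the finite-sample r² floor of ~1/(n−1).

Each row of the genotype matrix is a maternal parent of one half-sib family;
within-family segregation is not simulated. True breeding values are a sum
over `n_qtl` randomly placed markers with normal effects, standardized to
unit variance.

`simulate_trial_phenotypes` generates plot scores on a 0–20 scale as
`clip(10 + 2·latent, 0, 20)` where
`latent = BV + location + block(location) + family×location + residual`.
The family×location and residual variances are set from `h2_target = t` via
`D = var(BV)(1−t)/t`, split as `σ²_fl = D·l/2` and `σ²_ε = D·l·r/2` for `l`
locations and `r` blocks, so the family-mean heritability
`σ²_f / (σ²_f + σ²_fl/l + σ²_ε/(lr))` equals `t` in expectation (clipping at
the scale boundaries attenuates it slightly; the tests allow ±0.1).

`assign_geography` places populations uniformly over latitude 27–45°N and
signed longitude −100 to −76°E and generates a minimum winter temperature
`20 − 0.9·lat + N(0, 2²)`, giving a latitude–temperature correlation near
−0.9. With `geo_gradient = (g_lat, g_lon)` the breeding values are shifted
by the centred `g_lat·lat + g_lon·lon` of the individual's population.

`simulate_allelic_depths` draws, at each heterozygous call, a total depth
`~ Poisson(mean_depth)` and reference reads `~ Binomial(total, f)` with
`f = 0.5` for tetraploids (disomic behaviour) and `f ∈ {0.25, 0.5, 0.75}`
with equal weights for octoploids.

All stages draw from independent, reproducible streams derived from the
config seed via `SeedSequence(seed, spawn_key=(stage,))`.

## Marker QC

A marker survives iff (all strict) missingness < 0.20, minor-allele
frequency > 1/(2N) with N the total panel size, and the one-degree-of-freedom
Hardy–Weinberg chi-squared p-value > 1e-4. Missingness is computed as the
exact fraction `(N − n_obs)/N` so boundary cases (e.g. exactly 20%) are not
lost to floating-point rounding. Remaining missing calls are imputed with
the per-marker mean dosage, over the whole panel or within population
labels; imputation preserves the per-marker mean.

## Relatedness

The genomic relationship matrix is VanRaden's method 1,
`K = WWᵀ / (2Σp(1−p))` with `W` the panel-frequency-centred dosages;
rows sum to ~0 by construction. IBS is the mean over markers of
`1 − |dᵢ−dⱼ|/2`. PCA is the SVD of the centred dosage matrix with a
deterministic sign convention (largest-magnitude loading positive).

## Trial mixed model (REML)

`fit_random_model` fits `y = 1μ + Σ Zₜuₜ + e` with independent random terms
by REML on Henderson's mixed-model equations. The restricted likelihood is
evaluated through the determinant identity

```
−2ℓ_R = (n−p)ln 2π + (n−p−q)ln σ²_e + Σₜ qₜ ln σ²ₜ + ln|C| + y′Py
```

(`C` the MME coefficient matrix), which the tests verify equals the dense
form `−½[(n−p)ln2π + ln|V| + ln|X′V⁻¹X| + y′Py]` to 1e-8. Estimation is EM
(cheap, monotone) for up to 200 iterations, then a Nelder–Mead polish of the
restricted likelihood on the log-variance scale; EM alone converges
sublinearly near zero-variance boundaries, and the polish fixes that without
sacrificing EM's robust global behaviour. Components below 1e-8·var(y) are
reported as exactly 0. Terms confounded with the residual (one level per
record) or duplicating another term's grouping are rejected with an error.

## GBLUP

`fit_gblup` fits `y = 1μ + u + e`, `u ~ N(0, Kσ²_u)`, by profiling the
restricted likelihood over `λ = σ²_e/σ²_u` on the eigenbasis of `K`
(one eigendecomposition; O(n) per candidate λ). The search is bounded
minimization on `log λ ∈ [−10, 10]` guarded by a 21-point coarse grid
against local optima. Genomic heritability is `σ²_u/(σ²_u+σ²_e)`.
Prediction into unobserved individuals uses
`û_test = K[test,train](K_tt + λI)⁻¹(y_train − μ̂)`, which the tests verify
equals ridge regression on centred markers with penalty `λ·c`.

`cross_validate` runs replicated k-fold CV (fold sizes differ by at most
one; for n = 368, k = 5 the sizes are {74, 74, 74, 73, 73}), reporting
per-replicate Pearson accuracy and the accuracy of replicate-averaged GEBVs.
CV accuracy on pure-noise responses has a small negative bias — a known
property of correlating out-of-fold predictions with the full response —
so "null" checks are on the mean over draws, within ±0.1.

## GBLUP-MPM

The population kernel is the Matérn correlation
`K(d) = 2^{1−v}/Γ(v) (√(2v)d/h)^v K_v(√(2v)d/h)` over Euclidean distances
between standardized PC scores, computed in log space; tiny scaled
arguments where the Bessel function overflows map to the d→0 limit of 1.
`v = 0.5` gives `exp(−d/h)` (verified to 1e-12); `v → ∞` approaches the
Gaussian kernel. The working covariance is the Schur product `H = Ω∘G`,
PSD whenever both factors are. `(v, h)` are estimated by Nelder–Mead on the
log scale inside `v ∈ [0.05, 50]`, `h ∈ [1e-3, 1e3]`, starting at
(0.5, 0.5) with jittered restarts when the optimum lands on a bound; the
GBLUP-equivalent candidate (Ω = 1) is always evaluated and kept when
better, so ℓ_MPM ≥ ℓ_GBLUP holds on every fit by construction. The number
of PCs defaults to those individually explaining > 5% of variance.

## Bayesian whole-genome regression

Single-site Gibbs samplers for `y = 1μ + Za + e`, markers centred
internally. BayesA gives each marker its own variance with a
scaled-inverse-chi-squared prior (df 4.2); BayesB adds a point mass at zero
with prior probability π = 0.95, sampling inclusion from the exact log-odds;
the Bayesian lasso uses the Park–Casella hierarchy (inverse-Gaussian draws
for 1/τ², Gamma hyperprior on λ²). Prior scales follow the
proportion-of-variance heuristic with r² = 0.5. Chain defaults are 20 000
iterations / 5 000 burn-in; the test suite uses 1 500–4 000, which suffices
for the properties checked. Fixing the marker and residual variances
degenerates BayesA into a Gibbs sampler for ridge regression; the tests
verify the posterior means match the closed-form ridge solution.

## Ploidy inference

Heterozygous-site reference-read fractions (total depth ≥ 10) concentrate
near 0.5 for tetraploids and near {0.25, 0.5, 0.75} for octoploids. An
individual with ≥ 200 qualifying sites is labelled by comparing the
histogram mass within ±0.08 of 0.25/0.75 against the mass within ±0.08 of
0.5; ties and thin data are "ambiguous". At 20× depth the classifier is
≥ 95% accurate on simulated panels, and accuracy is non-decreasing in depth.

## Geographic validation

Adjusted GEBVs are population least-squares means from the one-way model
(equal to within-population arithmetic means). Correlation significance
uses the two-sided t-based critical value `|r| = t_{α/2,n−2}/√(t² + n − 2)`
(0.198 at n = 168, α = 0.01). The multiple regression of adjusted GEBV on
latitude and signed longitude deliberately excludes minimum temperature
whenever |r(min_temp, latitude)| > 0.8, since a collinear predictor makes
the coefficients uninterpretable. Longitude is signed degrees East
(negative across the USA): a breeding value rising from west to east has a
positive coefficient on the signed value.

## Problem sizes and runtime

Defaults target a few hundred families and a few thousand markers on one
CPU: the full test suite runs in ~2 minutes and the acceptance script in
~15 seconds. Spectral REML is O(n³) per fit from one eigendecomposition;
cross-validation refits per fold; the Gibbs samplers are O(n·m) per
iteration in pure NumPy.

## Limitations

- No linkage disequilibrium along chromosomes in the generator, so LD-decay
  analyses of simulated data only exhibit the sampling floor.
- Half-sib families are represented by the maternal genotype; no
  within-family Mendelian sampling.
- Score clipping at 0/20 slightly attenuates realized heritability relative
  to the target.
- The trial mixed model handles independent random factors only (no
  covariance between terms, no kernel-valued terms — use `fit_gblup` /
  `fit_mpm` for those).
- The MPM kernel search is a local optimizer with restarts, not a global
  one; the GBLUP fallback bounds the downside but a better interior optimum
  can in principle be missed.
- Ploidy calls assume the two-class tetraploid/octoploid mixture; other
  cytotypes are not modelled and surface as "ambiguous" at best.
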