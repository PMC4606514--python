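# Methods

## The problem

Genomic selection predicts the additive genetic merit (GEBV) of an
individual from genome-wide SNP genotypes, using a reference population in
which both genotypes and a quantitative response (phenotypes, EBVs, or
deregressed proofs) are available.  This package implements a Bayesian
whole-genome regression in which the prior probability that a marker has no
effect is *locus-specific* — derived from the trait's own genetic
architecture as seen by single-marker ANOVA — together with the standard
baselines (GBLUP, BayesA, BayesB) and the cross-validation protocol used to
compare them.

## Models

### GBLUP

    y = 1 μ + u + e,   u ~ N(0, σ²_u G),   e ~ N(0, σ²_e I)

`G` is the genomic relationship matrix built by VanRaden's first method:
`G = WW' / (2 Σ_j p_j(1 − p_j))` where `W` holds genotype codes 0/1/2
centered by twice the observed allele frequency of each marker.  We use
observed (training-set) frequencies, add `blend_epsilon = 1e-6` to the
diagonal to guarantee invertibility (negligible for predictions, but it
does perturb exact algebraic identities at the 1e-6 level — the
GBLUP↔RRBLUP equivalence test therefore runs unblended), and estimate
σ²_u, σ²_e by REML.  REML works in the eigenbasis of `G`: the residual
variance is profiled out and the restricted likelihood is optimised over
log κ, κ = σ²_u/σ²_e, on the bounded interval [−12, 12]; a solution at the
lower bound is reported as a boundary estimate σ²_u = 0.  Variance
components are re-estimated inside every training fold.  Predictions for
unphenotyped individuals propagate through the off-diagonal block of `G`
computed with training-set frequencies:
`û_new = σ²_u G_new,obs V⁻¹ (y_obs − μ̂)`, which is algebraically identical
to building one all-individuals `G` and solving the mixed-model equations
with masked responses.

### Marker model (BayesA / BayesB / BayesB-π)

    y = 1 μ + Σ_j w_j g_j + e,   g_j | σ²_gj ~ N(0, σ²_gj)

The marker-variance prior is scaled inverse chi-squared, σ²_gj ~ x⁻²(ν, S)
with ν = 4.234 and S = 0.0429 (a draw is S/χ²_ν); the residual variance
carries x⁻²(−2, 0), making its full conditional x⁻²(n − 2, e'e).  The
Gibbs sweep updates, in order: the marker variances, the residual variance,
the overall mean from N((1'y − 1'Wg)/n, σ²_e/n), and the marker effects
from their conjugate normal conditionals.

BayesB adds a point mass: σ²_gj = 0 with prior probability π (0.95 by
default).  The conjugate variance update cannot reach the point mass once
g_j ≠ 0, so variance and effect are updated jointly by a per-locus
Metropolis-Hastings run (default 100 cycles per locus per sweep).  Each
cycle draws a uniform gate α; with probability 1 − π_j a fresh variance is
proposed from the slab x⁻²(ν, S), otherwise zero is proposed.  Because the
proposal distribution is the mixture prior itself, the MH acceptance
probability reduces to the marginal likelihood ratio with g_j integrated
out,

    L(σ²) : y_adj ~ N(0, σ² w_j w_j' + σ²_e I),

evaluated in O(1) per cycle from the three scalars w_j'w_j, w_j'y_adj and
y_adj'y_adj via the rank-one determinant and Sherman–Morrison identities
(unit-tested against dense multivariate-normal evaluation).  After the
cycles, g_j is redrawn from its conditional if the variance is positive,
else set to zero.  An alternative convention in which a closed gate leaves
the variance untouched entirely (rather than proposing zero and letting the
likelihood ratio decide) is available as `gate_mode="skip"` for sensitivity
analysis; the two differ only in how often the chain proposes an exit from
the model.

BayesB-π is the same sampler with a per-marker π vector.  The vector comes
from the training data: a one-way fixed-effect ANOVA of the response on
each marker's genotype classes gives p-values, ω = −log₁₀(p), and

    π_i = (max ω − ω_i) / (max ω − min ω),

so the most significant marker gets π = 0 (proposed every MH cycle) and the
least significant π = 1 (never proposed).  Ties at the extremes share the
extreme values.  A p-value floor of 1e-300 keeps ω finite under numerical
underflow.  If every ω is equal (no architecture signal at all — a
degenerate case) the transform falls back to the constant π = 0.95 with a
warning.  Monomorphic markers, whose ANOVA is undefined, carry a sentinel
that maps to ω = 0, i.e. they are treated as maximally non-significant.

### Numerical and implementation choices

* Genotype columns are centered by 2p_j (training frequencies) before
  sampling; this only changes the interpretation of μ and is numerically
  safer than raw 0/1/2 coding.  Responses are z-scored by default inside
  the Bayesian estimators, and S = 0.0429 is used as-is on that scale.
* Chains are initialised at μ = ȳ, g_j = 0.01, σ²_gj at the prior mean,
  σ²_e at half the phenotypic variance; defaults are 10,000 sweeps with
  2,000 burn-in.  Post-burn-in samples are averaged into posterior-mean
  effects and per-marker inclusion frequencies.  No convergence diagnostics
  are applied beyond an effective-sample-size helper; chain length is fixed
  a priori.
* The production sweep batches all uniform/chi-squared proposal draws per
  sweep and skips residual updates for loci that stay excluded; it is
  algorithmically identical to the per-locus update primitive (same
  proposals, same acceptance rule) and is cross-checked against it in
  tests.  An optional per-locus counter-based RNG mode (`locus_keys`) makes
  the chain equivariant under marker permutation, which is used to test
  order-independence.
* A single seeded generator drives each chain; every stochastic API takes
  an explicit seed.

## Single-marker ANOVA

The association scan fits y = Xb + Zg + e one marker at a time, treating
the genotype codes as 2–3 factor levels (class-means model); with no
covariates X is the intercept and the test is the classic one-way F-test,
vectorised over markers through per-class counts and sums.  An
additive-dosage regression F-test is available as an option and gives
nearly identical results for common variants.  There is no kinship or
population-structure correction and no multiple-testing adjustment: π is a
monotone transform of the raw p-values, computed inside each training fold
only, so validation individuals never influence the prior.

## Synthetic data

The simulator generates genotypes in Hardy–Weinberg proportions at allele
frequencies drawn uniformly from a MAF range, independent across markers
(linkage equilibrium) by default; an optional Gaussian-copula block mode
adds within-block LD for realism checks.  Trait architectures: `n_qtl`
causal loci are chosen at random; one designated major QTL receives an
effect sized so its variance contribution 2pqa² is an exact chosen fraction
of the total genetic variance at the realised frequencies; the remaining
QTL effects are zero-mean Gaussian; Gaussian noise is added to hit a target
narrow-sense heritability.  Three presets mirror dairy-trait archetypes:
`mfp` (one gene at 30% of genetic variance, h² = 0.5 — a DGAT1-like
milk-fat-percentage architecture), `my` (one moderate 10% QTL plus many
small, h² = 0.5), and `scs` (purely polygenic, h² = 0.3, no major gene).

What the simulator does **not** emulate: linkage disequilibrium between
markers and unobserved causal variants (QTL are themselves markers here),
pedigree/family structure, selection, non-Gaussian residuals, and the
deregression process behind real EBV response variables.  Passing tests on
these data therefore demonstrate correctness of the algorithms and the
qualitative architecture-dependence of the methods, not field performance
on livestock data.

## Validation protocol

Optionally a subpopulation is drawn once without replacement; then repeated
shuffled k-fold cross-validation (5-fold × 20 repeats is the dairy-scale
design; 10-fold × 10 the pine-scale design).  Per fold, every
training-stage quantity — π vector, allele frequencies, variance
components, the chain itself — is recomputed on the training individuals
alone.  Accuracy is the Pearson correlation of GEBVs with held-out
responses; unbiasedness is the OLS slope relating them.  The unbiasedness
direction is genuinely ambiguous in the field: we default to regressing
GEBVs on responses (the literal protocol) and also report the conventional
response-on-GEBV slope in an extended column.  Mean ± SE aggregates are
taken over all repeat × fold records; trait-level "Mean" rows average the
per-subpopulation means.  Improvement of a method over a baseline is
β = (acc_new − acc_base)/acc_base × 100%.

## Problem sizes used in the shipped studies

The test-suite and acceptance-script studies run at desk scale, chosen so a
single CPU completes them in minutes while the contrasts of interest remain
resolvable: parameter-recovery runs use n = 500 individuals × m = 1000
markers with 2,000 sweeps and 10 MH cycles; the cross-validation contrasts
use n = 500 (major-QTL trait) or n = 300 (polygenic trait) × m = 300 with
500-sweep chains and 5 MH cycles, 10–20 replicates of 5-fold CV.  At these
settings the locus-specific prior shows the expected directional advantage
on major-gene architectures, and GBLUP remains competitive on purely
polygenic ones; magnitudes are smaller than what longer chains on
42k-marker panels produce and are not comparable to published livestock
results.

## Known limitations

* π is treated as data-derived input, not sampled (no BayesCπ/BayesDπ).
* The ANOVA scan ignores relatedness; in strongly structured populations
  the resulting π vector will absorb structure signal.
* REML is single-trait, intercept-only fixed effects.
* Mean imputation of missing genotypes only; no LD-aware imputation.
* The min-max π transform is sensitive to the single most significant
  marker (it anchors π = 0); the optional binned transform
  (`bayesbpi.anova.binned_pi`) trades that sensitivity for user-chosen
  p-value classes.
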