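# Methods

`ovinepred` implements a complete desk-scale genomic-prediction workflow for
multi-breed livestock populations: a population simulator, SNP/sample QC,
genomic and pedigree relationship matrices, REML variance components, GBLUP
and BayesR prediction, and relatedness-stratified validation. This note
documents the models, the defaults and why they were chosen, the numerical
choices, and what the synthetic data can and cannot show.

## The mixed model

All analyses share one linear mixed model:

    y = Xb + Z1 a + W w + Z1 Q q + Z2 s + e

- `y`: trait records, one per animal (phenotypic variance normalized to 1 in
  simulation, so variance components read as fractions).
- `b`: fixed effects — birth type, rearing type, gender, age at measurement
  (centered), weight at measurement when present, and contemporary group
  (flock x birth year x management group). Categorical covariates are
  dummy-coded against a dropped reference level.
- `a ~ N(0, K sigma_a^2)`: additive genetic effects, with `K` either the
  pedigree numerator relationship matrix `A` or the marker-based `G`.
- `w ~ N(0, I sigma_w^2)`: maternal effects, one level per dam. Animals with
  an unknown dam get an all-zero incidence row and are flagged.
- `q ~ N(0, I sigma_q^2)`: breed effects, entering through the pedigree
  breed-proportion matrix `Q` (rows sum to 1). Breed effects are random, as
  the model equation is written, even though many packages treat breed as
  fixed. When `Q` has rank 1 (single breed) the term is confounded with the
  intercept and dropped; a test verifies predictions are unchanged.
- `s ~ N(0, I sigma_s^2)`: sire-by-flock interaction, a
  genotype-by-environment proxy.
- Heritability is `sigma_a^2 / (sigma_a^2 + sigma_w^2 + sigma_s^2 +
  sigma_e^2)`. Between-breed variance is *not* within-population genetic
  variance, so `sigma_q^2` is excluded from the denominator. This was a
  genuinely open choice; the alternative (including it) changes h2 little
  when breed variance is small.

## Relationship matrices

`G = MM' / (2 * sum_j p_j (1 - p_j))` (VanRaden method 1) with `M` entries
`2 - 2p_j`, `1 - 2p_j`, `-2p_j` for counted-allele dosages 2/1/0 and `p_j`
the observed counted-allele frequency. Columns of `M` sum to zero, so all
entries of `G` sum to zero; mean diagonal ~ 1 and mean off-diagonal ~ 0 are
the scale diagnostics that make variance components under `A` and `G`
comparable. Monomorphic SNPs contribute nothing to numerator or denominator.
Missing genotypes are mean-imputed per SNP (centered entry 0), which
preserves `p_j` and adds no spurious relationship. By default frequencies
come from all supplied individuals (reference + validation); a `freqs`
argument allows reference-only frequencies.

`A` is built by the tabular method (`A_ii = 1 + 0.5 A_sire,dam`); it is
cross-checked against a brute-force gene-dropping identity-by-descent
simulator in the tests.

Relatedness stratification of validation animals: "high" when the mean of
the 30 largest genomic relationships to the reference is >= 0.20; "low" when
no relationship exceeds 0.10; "neither" otherwise. With fewer than 30
reference animals all relationships are used and a warning is logged.

## Quality control

SNP rules run in a fixed order, and each removal is attributed to the first
rule that fired: chromosome exclusion (X/Y) -> call rate < 0.90 -> mean
per-genotype quality score < 0.6 (only when a quality channel is supplied;
the simulator produces none) -> per-SNP observed heterozygote fraction
outside the panel mean +/- 3 SD -> MAF < 0.01 -> Hardy-Weinberg p < 1e-15
(chi-squared with 1 df, switching to the exact conditional test when any
expected genotype count is below 5). The heterozygosity rule is iterated to
a fixed point so that re-running QC on its own output is a no-op; a single
pass with statistics recomputed on survivors would not be idempotent. (The
later MAF/HWE removals can in principle perturb the heterozygosity panel
statistics on a re-run; with a 3 SD band this is negligible in practice.)
The heterozygosity rule uses observed heterozygosity; expected
heterozygosity is the documented alternative.

Duplicate samples: pairwise Pearson correlation of 0/1/2 calls over jointly
non-missing SNPs; at r >= 0.98 the later-listed sample is removed, so
transitive groups keep exactly their first member. Pairs with fewer than 100
overlapping SNPs are skipped with a logged warning. Sample call-rate
filtering is deliberately not implemented.

## REML

Variance components are estimated by average-information REML. The
restricted likelihood is evaluated in the phenotypic-covariance form
(`V = sum_i theta_i Z_i K_i Z_i' + theta_e I`, dense Cholesky): at the
record counts this pipeline targets (n up to a few thousand) the V form is
direct and transparent, and the MME form's asymptotic advantages never pay
off. AI updates use step-halving whenever a step would lower the
likelihood; any step proposing a negative component falls back to the
EM-type multiplicative fixed point `theta_i <- theta_i * (y'P V_i P y) /
tr(P V_i)`, which is positive by construction and shares the score's
stationary points. Components are floored at 1e-8 of total variance.
Convergence: relative log-likelihood change < 1e-8 and projected gradient
norm < 1e-6 (scaled); max 200 iterations, non-convergence flags the result
rather than raising. Starting values: half the phenotypic variance to the
residual, the rest split equally. SEs come from the inverse AI matrix;
h2 SE by the delta method. The optimizer is validated against a dense 41x41
grid search of the restricted likelihood on a two-component model.

Identifiability caveat: with mutually unrelated individuals `G ~ I` and the
additive and residual components are nearly unidentifiable; parameter-
recovery statements (e.g. "pure noise gives h2 ~ 0") hold on populations
with family structure, which is what the simulator produces.

## GBLUP

Henderson's mixed-model equations at fixed variance components, with
unphenotyped animals (validation sires) receiving BLUPs through their
relationship rows. Marker-based `G` is singular by construction (the
centered coding removes one dimension), so `K^-1` uses a 1e-8 diagonal
ridge when an inversion-quality check fails, with a logged warning; the MME
are solved by LU with iterative refinement and the max relative residual of
the system is reported (must be < 1e-6). The solution is verified against
ridge SNP-BLUP back-solved to animals (exact equivalence) and against a
hand-assembled 4x4 toy system. Reliability is `1 - PEV_i / (sigma_a^2
K_ii)` from the inverse coefficient matrix.

## BayesR

SNP effects follow a four-component normal mixture with variances
`(0, 0.0001, 0.001, 0.01) x sigma_g2`, where `sigma_g2` is the assumed
total genetic variance taken from the GREML fit. `sigma_g2` stays fixed by
default; `sample_sigma_g2=True` re-samples it from its scaled-inverse-
chi-squared full conditional (both behaviors exist because either reading
of "starting values taken from GREML" is defensible). Mixture proportions
carry a Dirichlet(1,1,1,1) prior. Default chain: 50,000 iterations, 10,000
burn-in, thinning 10; posterior summaries are means over kept samples.
Per iteration the sampler (i) block-samples fixed effects, (ii) samples
each non-SNP random term and its variance (scaled-inverse-chi-squared,
nu = 4, scale set so the prior mode matches the 5%-of-variance starting
value), (iii) sweeps SNPs in a freshly seeded random order — membership from
the marginal likelihood of `x_j'r`, then the effect from its Gaussian full
conditional, residual updated incrementally — (iv) draws proportions from
Dirichlet(alpha + counts), and (v) draws the residual variance. The sweep
is JIT-compiled (numba) with all randomness pre-drawn from the single seed,
so chains are bit-reproducible. Diagnostics: effective sample size of the
residual variance and of the non-null SNP count (initial-positive-sequence
estimator, implemented in-house), and an end-of-chain residual rebuild that
must match the incrementally updated residual within 1e-6.

Degenerate-prior oracles anchor correctness: proportions pinned to the null
component give exactly zero effects; pinned to a single component whose
variance equals the SNP-BLUP value, the posterior-mean GBVs reproduce GBLUP
(r >= 0.99).

## Validation

Accuracy is the Pearson correlation of predicted breeding values with
progeny-test EBVs (or true breeding values on simulation), per group, with
SE `sqrt((1 - r^2)/(n - 2))` and the OLS slope of EBV on GBV as the
dispersion-bias measure. An optional strain adjustment removes group means
over a strain label from both variables before correlating (fixed-effect
residualization) — the guard against pooling divergent strains inflating
within-breed accuracy. Panel comparisons report per-stratum accuracy
differences with a seeded paired-bootstrap percentile interval (1000
resamples); the bootstrap is an addition beyond the point estimates, since
accuracy differences without uncertainty are uninterpretable.

## The synthetic population

The generator emulates the study system: four breeds (Merino dam base,
Border Leicester maternal, Poll Dorset / White Suffolk terminal), a
crossbred reference (40% Merino-, 20% maternal-, 40% terminal-sired by
default), eight flocks, two marker densities at a ~1:10.5 SNP ratio
(density_ratio 0.095), trait h2 targets in the 0.13-0.88 range the traits
span, and progeny-test EBVs for purebred validation sires.

Mechanics and defaults:

- **Haplotype engine**: per breed, a Wright-Fisher population of
  `effective_size` (default 100) diploids evolves from a shared ancestral
  pool (frequencies uniform on 0.1-0.9) for `divergence_generations`
  (default 50), with recombination as the Markov switch process equivalent
  to a Haldane crossover process at marker resolution; 10 synthetic
  chromosomes of 1 Morgan. Drift both differentiates breeds (F_ST grows
  with divergence time; tested with a Hudson estimator) and builds
  within-breed LD. Defaults were chosen to give F_ST and LD in the range a
  sheep geneticist would call plausible at this marker density, and are not
  revisited per experiment.
- **QTL**: a random subset of dense-panel loci (default 500). Architectures:
  `gaussian` (N(0,1) effects), `few_large` (one in ten QTL carries a 10x-SD
  effect), `mixture` (three non-null scales, BayesR-like). Effects are
  rescaled once so founder TBV variance equals the target additive
  variance exactly. QTL are removed from both genotyping panels by default
  so prediction works through LD — the premise under study; `qtl_observed`
  keeps them on the dense panel only.
- **Validation sires**: half are founder males used as sires of reference
  progeny (genetically close, ~20 progeny each as in an AI-linked scheme);
  half are bred `distant_generations` (default 3) further down the
  within-breed line with no reference progeny (genetically remote). This is
  what makes the high/low relatedness strata non-empty at desk scale.
- **Phenotypes**: fixed-effect sizes are modest by design (each at most 0.5
  phenotypic SD; contemporary-group SD 0.25) since no real magnitudes are
  available. Breed effects are drawn `N(0, var_breed)` and, like maternal
  and sire-by-flock draws, the realized contribution vector is rescaled so
  its sample variance over phenotyped animals matches the configured
  fraction exactly (a rank-deficient `Q` would otherwise shrink the breed
  contribution unpredictably). The residual is rescaled the same way, so
  realized variance fractions are exact and only the TBV fraction is
  stochastic. The `h2 = 1, all other fractions 0` boundary is allowed and
  yields `y == tbv` exactly.
- **Progeny-test EBVs**: `ebv = acc^2 tbv + acc sqrt(1 - acc^2) sigma_a z`
  with `acc` the half-sib progeny-mean reliability
  `sqrt(0.25 n h2 / (1 + 0.25 (n - 1) h2))`, so `corr(ebv, tbv) = acc` by
  construction. With the default 60 progeny and trait h2 0.3-0.5 this puts
  accuracies in the 0.85-0.95 band typical of progeny-tested sires. The
  generative model is a package choice; only the accuracy range is
  externally constrained.

What passing tests on this data do **not** show: the simulator has no
genotyping error (beyond the optional quality channel), no selection, no
real ovine map, equal-frequency ancestral alleles rather than an
ascertained SNP chip, and breed divergence by pure drift without migration
or admixture. Absolute accuracies therefore do not transfer to real sheep
data; the qualitative contrasts (density gains concentrated in
low-relatedness animals, BayesR vs GBLUP by architecture, within- vs
across-breed prediction) are the reproducible content.

## Problem sizes in the shipped tests

Simulations in the test-suite and acceptance checks use reference sizes of
150-2000 animals and panels of 400-5000 SNPs, with 10 seeded replicates for
the stochastic pattern checks — sizes chosen so each check isolates its
effect at desk scale. BayesR chains in tests run 3,000-20,000 iterations;
the 50,000/10,000 default matches the analysis setting and is what the CLI
uses.

## Known limitations

- Single-trait only; no repeated records; homogeneous residual variance.
- No single-step (H-matrix) evaluation: every animal in the pipeline is
  genotyped, so it is not needed.
- Genotype imputation is out of scope; inputs must be complete or are
  mean-imputed.
- REML's dense-V evaluation is cubic in records; beyond ~5000 records an
  MME-based evaluation would be the right replacement.
- The duplicate-sample scan is O(n^2 m) when missingness forces pairwise
  masking.
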