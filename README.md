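# ovinepred

Genomic prediction for multi-breed livestock populations, built around the
sheep-breeding setting: a large crossbred reference population (Merino dam
base with maternal and terminal sire breeds), genotyped at a moderate and a
high marker density, and purebred industry sires with accurate progeny-test
EBVs serving as the validation benchmark. The package is for quantitative
geneticists who want a fully tested, reproducible desk-scale version of this
workflow — including the data: a population simulator generates genotypes,
pedigree, phenotypes and validation EBVs under known truth, so every stage
can be verified.

## What it computes

All components share one mixed model,

&nbsp;&nbsp;&nbsp;&nbsp;**y** = **Xb** + **Z**₁**a** + **Ww** + **Z**₁**Qq** + **Z**₂**s** + **e**,

with fixed effects **b** (birth type, rearing type, gender, age,
contemporary group), additive genetic effects **a** ~ N(0, **K**σ²ₐ) for
**K** the pedigree (**A**) or genomic (**G**) relationship matrix, maternal
effects **w**, breed effects **q** through the breed-proportion matrix
**Q**, and sire-by-flock effects **s**.

- `simdata` — multi-breed population simulator (Wright–Fisher gene-dropping
  with recombination, configurable QTL architectures, two marker densities,
  progeny-test EBVs for validation sires).
- `qc` — SNP filters (call rate, quality score, heterozygosity, MAF,
  Hardy–Weinberg, chromosome exclusion) and duplicate-sample removal, with
  per-rule attribution.
- `relmat` — VanRaden **G** = **MM**′/2Σpⱼ(1−pⱼ), tabular **A**, scale
  diagnostics, and relatedness stratification (top-30 mean ≥ 0.20 = high,
  max ≤ 0.10 = low).
- `reml` — AI-REML with EM fallback for the five variance components and
  h² with delta-method SE.
- `gblup` — Henderson mixed-model equations; GBVs for unphenotyped
  validation sires; PEV-based reliabilities.
- `bayesr` — Gibbs sampler for the four-component SNP-effect mixture
  (variances 0, 0.0001, 0.001, 0.01 × σ²_g; Dirichlet prior on
  proportions).
- `validate` — accuracy r with SE √((1−r²)/(n−2)), regression slope of EBV
  on GBV (dispersion bias), strain adjustment, and panel comparisons per
  relatedness stratum with bootstrap intervals.
- `pipeline` / `ovinepred` CLI — the end-to-end experiment from one YAML
  config, with content-addressed stage caching.

See `docs/methods.md` for the models, defaults and numerical choices, and
`examples/` for one narrative script per capability.

## Worked example

`examples/04_reml_and_gblup.py` simulates a four-breed population (800
reference animals, 2000 dense-panel SNPs, simulated h² = 0.3 with QTL off
the genotyping panel), fits REML under **G**, predicts 40 unphenotyped
validation sires and scores them against simulated progeny-test EBVs:

```
REML (6 iterations, converged=True):
  V_A=0.245  V_M=0.080  V_Q=0.245  V_SF=0.074  V_R=0.568
  h2 = 0.253 (SE 0.059); simulated h2 was 0.3
GBLUP accuracy vs progeny-test EBV over 40 sires: r = 0.43 (SE 0.15), regression slope 0.69
```

Reading the numbers: the marker-based additive variance (0.245) sits below
the simulated QTL-scale value (0.3) because the panel tags the unobserved
QTL imperfectly — the "missing heritability" the estimated SE correctly
brackets. The accuracy r = 0.43 is the empirical correlation between
genomic breeding values and the progeny-test benchmark; its SE follows the
√((1−r²)/(n−2)) formula. A regression slope near 1 would mean the GBV
spread is neither inflated nor shrunken.

From the shell, the same pipeline runs as:

```bash
ovinepred simdata --out-dir sim --seed 1
ovinepred qc --bed sim/dense --out sim/dense_qc
ovinepred relmat --bed sim/dense_qc --out sim/G
ovinepred run --config examples/experiment.yaml
```

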