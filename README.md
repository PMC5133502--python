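# famcombine

Combining family-based, gene-based rare-variant association tests into a
single permutation-calibrated p-value.

## The problem

Gene-based tests of rare-variant association come in two families: **burden
tests**, which collapse the per-variant signal into one weighted sum and are
powerful when causal variants act in the same direction, and
**variance-component tests** (SKAT-style), which aggregate squared
per-variant signals and are robust when effects go both ways. Which one is
more powerful depends on the (unknown) genetic architecture of each gene.
Running many tests and reporting the best p-value is anticonservative; with
8 independent tests, naive min-p thresholding at 0.05 would reject about
1 − 0.95⁸ ≈ 34% of null genes.

`famcombine` implements, for pedigree data with a quantitative trait, a
permutation framework that runs an arsenal of k tests and returns one valid
combined p-value that accounts for both multiplicity and the (typically
strong) correlation between the tests.

## The method

1. **Null model.** A linear mixed model
   `y = XB + g + e`, `g ~ N(0, σ_g²·2Φ)`, `e ~ N(0, σ_e²·I)`,
   is fitted by ML (or REML) via eigendecomposition of the additive
   relationship matrix `2Φ` derived from the pedigree. The whitened
   residuals `Σ̂⁻¹ᐟ²(y − XB̂)` are uncorrelated under the fitted model and
   therefore exchangeable across individuals, unlike the raw trait, which
   carries family structure.
2. **Score statistics.** For variant i, `U_i = (y − XB̂)′ Σ̂⁻¹ g_i`. Two
   weighting schemes — `w_i = Beta(MAF_i; a1, a2)` (default a1=1, a2=25)
   and `w*_i = 1/√(p_i(1−p_i))` — and powers 1–4 give 8 statistics:

   | burden-type | variance-component-type |
   |---|---|
   | `Q1 = \|Σ w_i U_i\|`, `Q3 = \|Σ w_i³U_i³\|` | `Q2 = Σ w_i²U_i²`, `Q4 = Σ w_i⁴U_i⁴` |
   | `Q1*`, `Q3*` (with `w*`) | `Q2*`, `Q4*` (with `w*`) |

   `Q2` corresponds to the famSKAT statistic; `Q1` to a classical weighted
   burden test.
3. **Combination.** The exchangeable residuals are permuted m times, all 8
   statistics are recomputed on each permutation (one matrix product per
   gene), each statistic column is converted to empirical rank p-values,
   each row is summarised by `S = min(p_1, …, p_k)`, and the combined
   p-value is `(1 + #{S⁽ʲ⁾ ≤ S⁽⁰⁾})/(m+1)`. Because every test sees the
   same permuted residuals, the null distribution of S reflects the
   inter-test correlation exactly.

A gene-dropping simulator (pedigrees, Mendelian genotypes, polygenic
traits with or without genic effects) and a study driver (type-I-error and
power experiments with exact binomial CIs) are included, so all evaluation
runs without any external data.

## Worked example

```python
import famcombine as fc

cfg = fc.SimConfig(n_families=4, h2=0.3, causal_fraction=0.5,
                   genic_variance=0.05, seed=3)
study = fc.simulate_study(cfg)                       # 168 people, 1 gene
fit = fc.FamilialLMM.from_phenotype_data(study.trait, study.kinship).fit()
print(fit.summary())
res = fc.FamilyCombinedTest(study.genotypes[0], fit).fit(m=1000, seed=1)
print(res.summary())
```

```
Familial linear mixed model (ML)
n = 168, covariates = 2
log-likelihood = -225.8528
sigma_g^2 = 0.384707   sigma_e^2 = 0.571011   h2 = 0.4025

        coef   std err
x0  0.181298  0.144041
x1  0.496012  0.071883

Combined family-based rare-variant test: gene GENE1
variants = 24, permutations = 1000, seed = 1

Q2     0.325674
Q2*    0.259740
Q1     0.232767
Q1*    0.203796
Q4     0.387612
Q4*    0.172827
Q3     0.240759
Q3*    0.080919

S_observed (min p) = 0.0809191
combined p        = 0.227772
```

The mixed model recovers the simulated covariate effect (0.5) and a
heritability near the generating value; the per-test rows are empirical
rank p-values of the 8 statistics, the most extreme of which (`Q3*`,
p ≈ 0.081) would look significant if cherry-picked, while the
permutation-calibrated combined p-value (0.23) correctly absorbs the
selection over 8 correlated tests.

The same pipeline is available from the shell:

```bash
famcombine simulate --out-dir demo --seed 3
famcombine run --vcf demo/study.vcf --ped demo/study.ped \
    --pheno demo/phenotypes.tsv --covar covar1 \
    --permutations 1000 --seed 1 --out demo/results.tsv
famcombine level --replicates 200 --permutations 1000 --seed 1 --out demo/level.json
```

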