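# Methods

## Model and assumptions

The phenotype is a quantitative trait on n related individuals with known
pedigree. The null model is the standard polygenic linear mixed model

    y = X B + g + e,    g ~ N(0, σ_g² · 2Φ),    e ~ N(0, σ_e² · I),

where Φ is the expected kinship matrix computed from the pedigree by the
parent-ordered recursion (φ = 0.5 on founder diagonals, φ(i,i) =
(1 + φ(father, mother))/2, φ(i,j) = (φ(father_i, j) + φ(mother_i, j))/2).
The covariance handed to the model is the additive relationship matrix 2Φ;
the proportionality constant between trait covariance and kinship is
absorbed into σ_g². Kinship is autosomal only (sex is parsed but unused),
between-family coefficients are exactly zero, and individuals appearing
only as parents are added internally as founders and marginalised out of
the returned matrix. A user-supplied square kinship matrix can override
the recursion (for genotype-based estimates produced elsewhere).

Assumptions worth stating: Gaussian trait given covariates, a single
polygenic random effect with homoscedastic residuals, and a regression
model that is correct under the genetic null — the permutation logic below
inherits exactly these assumptions.

## Fitting

With 2Φ = V D V′, the likelihood is profiled over the single variance
ratio δ = σ_g²/σ_e²: in the rotated basis each candidate δ is a weighted
least-squares problem, so one profile evaluation costs O(nc²) after the
one-off O(n³) eigendecomposition. The profile is maximised by bounded
Brent search over log δ ∈ [log 1e−6, log 1e6] with tolerance 1e−8; the
boundary σ_g² = 0 (OLS) is evaluated explicitly and preferred on ties, so
the returned log-likelihood never falls below the OLS log-likelihood.
ML is the default; REML is available by flag. σ_e² is floored at 1e−12
when the trait is degenerate (zero residual variance) so that Σ̂ stays
invertible. Missing phenotype/covariate rows are dropped listwise with a
logged count before alignment with the kinship matrix.

## Exchangeable residuals

Permuting the raw trait breaks the family structure and inflates type I
error, so permutation operates on decorrelated residuals. The default is
the whitened vector z = Σ̂⁻¹ᐟ²(y − XB̂) (symmetric square root), which has
identity covariance under the fitted model and is therefore exchangeable;
z is additionally mean-centred so the permuted scores carry no intercept
leakage (centring shifts every permutation row by the same constant, so
the test remains exact). A `residual_kind="conditional"` switch instead
permutes y − XB̂ − ĝ (BLUP-adjusted residuals), a looser but common
reading; the whitened default is used everywhere in the reported
experiments.

## Score statistics and weights

For variant i with minor-allele dosage vector g_i, U_i = (y − XB̂)′Σ̂⁻¹g_i.
Weights are w_i = Beta-density(MAF_i; a1, a2) with the SKAT convention
a1 = 1, a2 = 25 by default, and w*_i = 1/√(p_i(1−p_i)). MAF is the overall
sample frequency (the case/control notion behind w* has no analogue for a
quantitative trait); dosages are oriented to the minor allele, which
affects burden signs only. Monomorphic variants are dropped with a logged
warning; fixed variants under w* get weight zero rather than infinity; no
MAF ceiling is applied by default (`max_maf` is available). The eight
statistics are the weighted power sums Q_d = |Σ (w_i U_i)^d| for d = 1, 3
and Q_d = Σ (w_i U_i)^d for d = 2, 4, each in plain and starred form.

## Permutation combination

Row 0 of the permutation table holds the observed statistics; rows 1..m
hold the statistics recomputed from permuted residuals. Nothing is
refitted per permutation — B̂, Σ̂⁻¹, weights and MAFs are those of the
observed fit — so the whole table for a gene is a single (m+1, n) × (n, p)
matrix product. Empirical p-values rank each column jointly over all m+1
rows, largest statistic = rank 1, ties sharing the maximum rank of their
group (conservative); p = rank/(m+1), which bounds p ≥ 1/(m+1) and makes
the per-test permutation test exactly valid. A `paper_rank` switch
reproduces the literal rank/m convention (capped at 1). The row summary
is S = min over the k p-values, and the combined p-value is
(1 + #{S⁽ʲ⁾ ≤ S⁽⁰⁾})/(m+1): small min-p = extreme, with the ≤ direction
(a `direction` switch retains the opposite reading). One shared
permutation stream per gene across all k tests is what lets the null
distribution of S absorb the inter-test correlation. Per-gene seeds are
derived as SeedSequence(master_seed, crc32(gene_id)), so genes are
independently reproducible and safely parallelisable.

## Synthetic data generator

The generator emulates a large extended-pedigree study of a
blood-pressure-like quantitative trait. Defaults: 20 three-generation
families of 42 (a founder couple, 5 married-in children, 6 grandchildren
per couple → 840 individuals); genes of 30 independent variants with MAF
uniform on [0.001, 0.05] plus an optional common-variant fraction;
polygenic heritability h² = 0.3 of a unit-variance trait; covariates are
an intercept plus one standard-normal covariate with effect 0.5. Founder
alleles are Bernoulli(MAF) and transmitted by Mendelian sampling (gene
dropping), so genotypes are Mendelian-consistent by construction. Causal
variants get β_v = c·|log10 MAF_v| (optionally random-signed under
`mixed_direction`), with c solved so the genic component explains a
target fraction (`genic_variance`) of the trait variance. A diastolic/
systolic pair is not simulated; a `mean_arterial_pressure` transform
((2/3)·DBP + (1/3)·SBP) is provided for users with real columns.

What the simulator does **not** emulate: linkage disequilibrium between
variants (sites are dropped independently), ascertainment of affected
families, genotyping error/missingness patterns, and real gene structure.
Passing level/power experiments here therefore demonstrate the validity
and robustness of the combination machinery under a correctly specified
polygenic model — not performance on any particular real data set.

## Experiment design and problem sizes

Type-I-error experiments fix the pedigree and genotypes and simulate 200
independent heritable, genotype-independent traits (h² = 0.3, 840
individuals, one ~30-variant gene, m = 1000 permutations, α = 0.05);
with 200 replicates the exact binomial 99% acceptance band around 0.05 is
(0.4%, 9.6%). Uniformity of the combined p-value is additionally checked
by a Kolmogorov–Smirnov test over 500 replicates at n = 200, m = 500, and
the multiplicity contrast (naive min-p over 8 independent tests rejecting
≈ 34% vs the calibrated combination holding 5%) is computed on simulated
independent statistic tables.

The weighting-robustness experiment uses two matched architectures on a
30-variant gene in which half the variants are common (MAF 0.2–0.5):
**rare-causal** (causal variants drawn from the rare half) and
**common-causal** (causal variants drawn from the common half), both with
genic variance 2% — chosen so the favoured test group sits in an
intermediate power regime (~0.4–0.8) where the contrast between weighting
schemes is measurable rather than saturated. Beta-density weights
essentially remove common variants (w(0.3)/w(0.005) ≈ 1/120), so they win
when the signal is rare and lose it entirely when the signal is common,
while 1/√(pq) weights standardise every variant and carry the common
noise; the combined test is expected to land between the best and worst
individual tests in both regimes. 100 paired replicates at m = 500 are
used per architecture.

Heritability recovery uses 500 simulated traits with true h² = 0.5 on the
default 840-person pedigree; kinship correctness is checked against a
gene-drop IBD estimator (100,000 drops) on a 14-member pedigree. Because
Monte-Carlo z-scores are compared across many matrix entries at once, the
oracle agreement bound is applied familywise (Bonferroni-adjusted max-|z|)
rather than entrywise; deterministic entries (founder pairs,
between-family zeros) must match exactly.

## Numerical choices and degenerate inputs

- Eigenvalues of 2Φ are clipped at zero; the trait simulator adds 1e−10
  jitter before Cholesky because 2Φ is only positive semidefinite.
- Score/statistic computations are exact vectorised forms of the defining
  sums; the test suite checks them against naive triple-loop
  re-implementations at 1e−10.
- An empty or all-monomorphic gene raises a gene-skip error; `run_genes`
  logs and skips such genes instead of failing the batch.
- m < 100 permutations triggers a logged warning; combined p-values are
  bounded below by 1/(m+1) by construction.
- Bit-for-bit reproducibility: all randomness flows through
  numpy SeedSequence spawning; identical seeds and inputs give identical
  results tables.

## Known limitations

Quantitative traits only (no GLMM for binary outcomes); a single random
effect; min-p is the only combination function (Fisher/Stouffer-style
alternatives would slot into the same permutation table); no adaptive
early stopping of permutations, so very small p-values are expensive; and
asymptotic p-values for the individual statistics are deliberately out of
scope — every p-value in this package is empirical.
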