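# Methods

## Statistical model

### Kinship and the correction factor

All tests treat the additive genotype of a variant as an exchangeable random
vector over the sample with correlation matrix K = 2Φ, where Φ holds
pairwise kinship coefficients φ(i, j) — the probability that randomly drawn
alleles from i and j are identical by descent. For outbred individuals the
correlation of minor-allele counts between relatives is exactly 2φ under
gene dropping, which is what the synthetic generator produces and what the
correction assumes about real data.

The case–control mean contrast cᵀx (c_i = 1/n_A for cases, −1/n_G for
controls) has variance σ²·cᵀKc instead of the independence value
σ²·(1/n_A + 1/n_G). The scalar

    P_corr = (cᵀ K c) / (1/n_A + 1/n_G)

is the unique factor restoring the null variance of any per-variant
contrast, and it reduces to 1 exactly for identity kinship. Because c is
built from the observed phenotype, P_corr automatically reflects how cases
cluster within families: related case–case or control–control pairs inflate
it, related case–control pairs deflate it (a parent–offspring case/control
singleton design gives P_corr = 0.5). A unit test verifies P_corr against
the empirical variance of the contrast over 10⁵ correlated draws.

Two constructions of Φ are provided and are interchangeable downstream:

* **Theoretical** — recursion over a topological order of the pedigree DAG:
  φ(i,i) = ½(1 + φ(f_i, m_i)) and φ(i,j) = ½(φ(f_i, j) + φ(m_i, j)),
  founders unrelated and non-inbred. Validated against a Monte-Carlo
  gene-dropping IBD oracle.
* **Estimated** — the robust pairwise moment estimator
  φ̂ = (N_AaAa − 2·N_AAaa) / (N_Aa(i) + N_Aa(j)) over sites called in both
  individuals (both-heterozygous and opposite-homozygote counts). It uses no
  allele frequencies, is invariant to allele relabelling, and recovers the
  theoretical matrix with mean absolute error < 0.02 from 5·10⁴ independent
  common sites. Negative estimates are retained by default because the
  P_corr quadratic form needs unbiased entries; a clamping flag exists. The
  diagonal is fixed at 0.5 (no inbreeding estimation — simulated founders
  are outbred).

### Gene-level tests

* **Generalized T²**: Hotelling statistic on the gene's variant columns with
  pooled within-group covariance S (denominator n − 2); T²/P_corr is
  referred to χ² with df = rank(S). Zero-variance columns are dropped
  first; a rank-deficient S is pseudo-inverted and df set to the rank, since
  the asymptotics are otherwise invalid when many extremely rare variants
  duplicate or vanish.
* **CMC**: columns with MAF strictly below the threshold are replaced by a
  single carrier indicator (≥ 1 minor allele at any rare site), columns at
  or above pass through; then the T² machinery. Thresholds 5% and 0.5% are
  the bundled defaults. As the threshold → 0 the test is identical to T²,
  and its df never exceeds the T² df.
* **χ²min**: per-variant 2×2 allele-count tables (minor/major × case/
  control). If every expected cell is ≥ 5, the Pearson χ²₁ statistic is
  divided by P_corr; otherwise the two-sided Fisher exact p is mapped to a
  χ²₁ quantile, deflated by P_corr, and mapped back — this choice makes the
  Fisher path agree with the Pearson path wherever both apply. The gene
  p-value is the minimum over variants with no multiplicity correction, so
  its type I error is inflated by construction; it is retained as the
  baseline the corrected tests are compared against. The allelic (2×2)
  rather than genotypic (2×3) table matches the mean-allele-count framing of
  the other tests and keeps the adjustment on 1 df.

MAF is computed on the full phenotyped analysis sample (cases and controls,
founders and non-founders); missing genotypes are mean-imputed per variant
before the matrix algebra, while carrier indicators and allele-count tables
use only called genotypes.

## Synthetic data generator

The generator emulates a multigenerational family study with a dichotomous
"ever-affected" phenotype:

* **Pedigrees** — per family a founder couple; every child marries a fresh
  founder spouse and each mating has 1 + Poisson(mean_sibship) children
  (never extinct). Twenty 3-generation families with mean_sibship 3 give
  ~850–900 individuals.
* **Genotypes** — gene dropping: founder alleles Bernoulli(MAF) per site,
  children inherit one uniformly chosen allele per parent. Sites are
  independent (no LD), Mendelian-consistent by construction.
* **Phenotype** — liability L = Σ β_j (g_j − 2p_j) + a + e with
  a ~ N(0, h²·2Φ), e scaled so Var(L) = 1, and case status L > Φ⁻¹(1 − prevalence).
  β_j = sqrt(v_j / (2 p_j (1 − p_j))) turns a target variance-explained v_j
  into an allelic effect. Up-to-4-wave longitudinal tables are written by
  replicating the binary status with configurable per-wave missingness.

Key defaults (all in `SimulationConfig`): prevalence 0.3 (a plausible adult
hypertension rate; configurable), liability heritability 0.3, founder MAF
log-uniform on [0.005, 0.05] so genes are dominated by rare variants, gene
sizes uniform on the configured range, one causal SNV per causal gene.

Per-causal-SNV variance explained is drawn from a gamma distribution with
mean 4·10⁻⁴ and SD 10⁻³, right-truncated at 9·10⁻³ by resampling. A gamma is
used because no normal distribution left-truncated at zero can have an SD of
2.5× its mean (the deep-truncation limit is exponential, SD = mean), whereas
the gamma reproduces these over-dispersed moments and the 0–0.9% range: many
effectively null "causal" SNVs with occasional larger effects. Under this
spectrum the power of every test at α = 0.05 is statistically
indistinguishable from its type I error — the central calibration fact the
acceptance suite checks.

What the generator does **not** emulate: linkage disequilibrium (an optional
haplotype-copying knob was considered and rejected to keep the null exactly
exchangeable), ascertainment of families through affected probands,
population stratification or cryptic relatedness between founders,
covariates (age, sex, medication), longitudinal phenotype dynamics, and
genotyping error. Consequently, a calibrated test here demonstrates
correctness of the pedigree correction, not robustness to stratification —
on real data an estimated kinship matrix is the safer choice precisely
because it absorbs structure the stated pedigree cannot.

## Numerical and design choices

* Pooled covariance uses within-group centering with denominator n − 2
  (classical two-sample Hotelling convention); the null-uniformity property
  test is the guard on this choice.
* Degenerate genes (all columns monomorphic) return p = 1, df = 0, flagged
  `untestable`, and are kept in results tables rather than dropped.
* Pedigree evaluation order is a topological sort (stdlib graphlib), which
  doubles as cycle detection; individuals referenced as parents without
  their own record are materialized as founders, and a half-missing parent
  pair gets a phantom founder (both logged).
* The Bonferroni threshold α/n_genes is kept as an exact rational value;
  rounding happens only in reports. Top-gene reporting uses a suggestive
  cutoff of p < 10⁻⁴ by default.
* Reproducibility: a single master seed is split into per-stage
  SeedSequence streams (pedigree, gene catalogue, gene drop, phenotype), so
  each stage is independently reproducible and identical configs give
  byte-identical outputs.
* Monte-Carlo oracle tolerances: single derived pairs are checked at 3
  standard errors; joint all-pairs matrix checks use a 4-SE band as a
  Bonferroni-style multiplicity adjustment over ~45 pairs.

## Problem sizes used in the test and acceptance runs

The reference null study uses 20 three-generation pedigrees (~880
individuals) and 2000 null genes of 2–20 SNVs; the power companion uses
1000 causal genes under the weak-effect spectrum. Kinship-estimator
recovery runs on 5·10⁴ independent common sites over three families. These
sizes make the binomial 3σ band around a 5% rejection rate ±1.5 percentage
points, tight enough to detect meaningful miscalibration while keeping a
full run in the minutes range on one CPU.

## Known limitations

* Covariate adjustment is out of scope: the statistics compare group means
  and have no regression layer.
* Genes with more than 200 SNVs are excluded by the default size filter;
  the asymptotics degrade there and a different method family is needed.
* The χ²min Fisher-path P_corr adjustment through the χ²₁ quantile is a
  modelling choice validated by simulation properties, not an exact finite-
  sample result.
* X-linked kinship, inbreeding-coefficient estimation, and identity-state
  (Jacquard) coefficients are not implemented.
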