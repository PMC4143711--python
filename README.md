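# famrare

Family-based rare-variant association tests for binary traits in complex
(multigenerational, non-nuclear) pedigrees, plus a synthetic family-study
generator for measuring their type I error and power.

Rare single-nucleotide variants (SNVs) carry too little evidence to test one
at a time, so gene-level SNV-set tests are the standard approach; in pedigree
samples the extra correlation between relatives must additionally be
absorbed, or the null distribution is wrong. `famrare` implements three
gene-level tests for a dichotomous phenotype (for example "ever-hypertensive"
across up to four longitudinal measurement waves), all corrected for
relatedness through the kinship matrix:

- **Generalized T²** — a Hotelling-style multivariate comparison of mean
  minor-allele counts between cases and controls over a gene's *t* variants.
  With mean contrast d = X̄_A − X̄_G and pooled within-group covariance S
  (denominator n − 2),

      T² = dᵀ [ (1/n_A + 1/n_G) S ]⁻¹ d,   T²/P_corr ~ χ²_t  under H₀.

- **CMC** (combined multivariate and collapsing) — variants with MAF below a
  threshold (5% and 0.5% cutoffs are bundled) are collapsed into a single
  carrier-indicator "super variant" before the same T² machinery, trading
  degrees of freedom for stability with very rare variants.

- **χ²min** — the smallest P_corr-adjusted single-marker p-value in the gene
  (Pearson χ² or Fisher exact on the 2×2 allele-count table), deliberately
  *not* corrected for the number of variants; it is included as the
  anticonservative baseline and its inflation is part of the test suite.

The correction factor is the variance inflation of the case–control mean
contrast under genotype correlation K = 2Φ (twice the kinship matrix): with
c_i = 1/n_A for cases and −1/n_G for controls,

    P_corr = (cᵀ K c) / (1/n_A + 1/n_G),

so an unrelated sample (K = I) gives P_corr = 1 exactly. Φ can come from
stated relationships (recursive pedigree kinship) or be estimated from dense
genotypes with a robust heterozygosity-ratio moment estimator; the two are
interchangeable everywhere downstream.

## Worked example

Simulate a 10-family study (200 genes, 5% causal), compute both kinship
matrices, run all tests under both, and evaluate:

```bash
famrare simulate --config config.yaml --out-dir sim
famrare kinship --mode theoretical --fam sim/pedigree.fam --out kin_theo.tsv
famrare kinship --mode estimated --vcf sim/genotypes.vcf --out kin_est.tsv
famrare test --vcf sim/genotypes.vcf --phenotype sim/phenotype.tsv \
    --genes sim/genes.tsv --kinship theoretical=kin_theo.tsv \
    --kinship estimated=kin_est.tsv --out results.tsv
famrare evaluate --results results.tsv --truth sim/truth.tsv --out-dir eval
```

with `config.yaml`:

```yaml
n_families: 10
n_genes: 200
snvs_per_gene_range: [2, 20]
causal_fraction: 0.05
seed: 42
```

This prints (abridged):

```
simulated 434 individuals, 2271 SNVs in 200 genes -> sim
  method kinship_mode   stratum  n_genes  n_significant  proportion_significant
      T2  theoretical noncausal      190              8                0.042105
CMC_0.5%  theoretical noncausal      190              9                0.047368
 CHI2MIN  theoretical noncausal      190             64                0.336842
      T2  theoretical    causal       10              0                0.000000
Bonferroni threshold 0.00025; 0 significant genes; reports in eval
```

Reading it: on null (noncausal) genes the kinship-corrected T² and CMC
reject at roughly the nominal 5%, while χ²min rejects a third of all null
genes — the multiplicity inflation it is designed to exhibit. Power on the
causal stratum is essentially nil because the simulated per-SNV effects are
weak (mean 0.04% of liability variance). `eval/correlations.tsv` shows
p-values under theoretical versus estimated kinship correlate at ≥ 0.999
here, so the two kinship routes are statistically interchangeable on clean
simulated data. `eval/screen.txt` applies the Bonferroni cutoff
(0.05 / 200 genes) and lists the top genes per method.

The same objects are available as a library (`simulate_study`, `run_study`,
`summarize_type1_power`, `pvalue_correlations`, `bonferroni_screen`, ...)
for scripted studies.

## Synthetic data

`famrare.synthetic_data` generates the full study: founder couples expanded
into multigenerational pedigrees, genotypes gene-dropped through the
pedigree from founder MAFs (no linkage disequilibrium), and a binary
phenotype from a liability-threshold model with a polygenic component
a ~ N(0, h²·2Φ) plus per-variant causal effects specified on the
variance-explained scale. Defaults: heritability 0.3, prevalence 0.3,
founder MAF log-uniform on [0.005, 0.05], causal-SNV variance explained with
mean 0.04% and SD 0.1%, truncated at 0.9%. See `docs/methods.md` for the
model, assumptions, and limitations.

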