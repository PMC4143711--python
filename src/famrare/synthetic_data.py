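"""Synthetic family study generator.

Produces multigenerational pedigrees, gene-dropped SNV genotypes, and a
dichotomous "ever-hypertensive"-style phenotype from a liability-threshold
model, with the statistical structure the family-based tests assume:

* pedigrees: per family, a founder couple; every child marries a new founder
  spouse and each mating produces 1 + Poisson(mean_sibship) children;
* genotypes: founder alleles are Bernoulli(MAF) independently per site (no
  LD), children inherit one uniformly chosen allele from each parent
  (Mendelian by construction);
* phenotype: liability L = sum_j beta_j (g_j - 2 p_j) + a + e with a
  polygenic term a ~ N(0, h2 * 2 Phi), residual e scaled so Var(L) = 1, and
  case status L > Phi^{-1}(1 - prevalence).

Per-causal-SNV effect sizes are drawn on the variance-explained scale from a
gamma distribution with mean 4e-4 and SD 1e-3, right-truncated at 9e-3 — a
spectrum of many near-zero effects with occasional ones up to ~0.9% of
liability variance.  (No normal distribution left-truncated at zero can have
SD = 2.5x its mean, so the over-dispersed gamma is used for these moments.)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .genotype_geneset import GeneSet, GenotypeMatrix, PhenotypeVector
from .pedigree_kinship import Individual, KinshipMatrix, Pedigree, theoretical_kinship

__all__ = [
    "SimulationConfig",
    "StudyData",
    "simulate_pedigrees",
    "gene_drop_genotypes",
    "draw_variance_explained",
    "simulate_phenotype",
    "label_causal_genes",
    "simulate_study",
    "write_vcf",
    "write_fam",
    "write_phenotype_waves",
    "write_gene_table",
    "write_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults give a null study: 20 three-generation families, rare variants
    (MAF 0.5%-5%, log-uniform), polygenic heritability 0.3 on the liability
    scale and prevalence 0.3, with no causal genes unless ``causal_fraction``
    is raised.
    """

    n_families: int = 20
    generations: int = 3
    mean_sibship: float = 3.0
    maf_range: tuple[float, float] = (0.005, 0.05)
    n_genes: int = 2000
    snvs_per_gene_range: tuple[int, int] = (2, 200)
    causal_fraction: float = 0.0
    causal_variance_mean: float = 0.0004  # per-SNV liability variance explained
    causal_variance_sd: float = 0.001
    causal_variance_max: float = 0.009
    polygenic_heritability: float = 0.3
    prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ParameterError(f"prevalence must be in (0,1): {self.prevalence}")
        if not (0.0 <= self.polygenic_heritability < 1.0):
            raise ParameterError(
                f"heritability must be in [0,1): {self.polygenic_heritability}"
            )
        if self.generations < 2:
            raise ParameterError("need at least 2 generations")
        if not (0.0 <= self.causal_fraction <= 1.0):
            raise ParameterError(
                f"causal_fraction must be in [0,1]: {self.causal_fraction}"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError(f"maf_range must satisfy 0 < lo <= hi <= 0.5")
        lo_s, hi_s = self.snvs_per_gene_range
        if lo_s < 1 or hi_s < lo_s:
            raise ParameterError("invalid snvs_per_gene_range")
        if min(self.causal_variance_mean, self.causal_variance_sd) < 0:
            raise ParameterError("causal variance moments must be >= 0")


@dataclass
class StudyData:
    """One simulated study: pedigree, genotypes, genes, phenotype, truth."""

    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    genesets: list[GeneSet]
    gene_table: pd.DataFrame
    phenotype: PhenotypeVector
    kinship: KinshipMatrix  # theoretical, from the generating pedigree
    variance_explained: np.ndarray  # per variant, liability scale
    truth: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.truth is None:
            per_gene_v = [
                float(self.variance_explained[g.variant_indices].sum())
                for g in self.genesets
            ]
            self.truth = pd.DataFrame(
                {
                    "gene": [g.gene_name for g in self.genesets],
                    "causal_flag": [int(g.causal_flag) for g in self.genesets],
                    "variance_explained": per_gene_v,
                }
            )


def simulate_pedigrees(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Generate ``n_families`` independent multigenerational pedigrees.

    Founders are unrelated; every child takes a new founder spouse and each
    couple has 1 + Poisson(mean_sibship) children.  Reproducible under the
    config seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    individuals: list[Individual] = []
    for fam in range(1, cfg.n_families + 1):
        fid = f"F{fam}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fid}_I{counter}"

        father0, mother0 = new_id(), new_id()
        individuals.append(Individual(father0, fid, None, None, 1))
        individuals.append(Individual(mother0, fid, None, None, 2))
        couples = [(father0, mother0)]
        for _ in range(cfg.generations - 1):
            next_couples = []
            for father, mother in couples:
                n_children = 1 + int(rng.poisson(cfg.mean_sibship))
                for _ in range(n_children):
                    child = new_id()
                    sex = 1 if rng.random() < 0.5 else 2
                    individuals.append(Individual(child, fid, father, mother, sex))
                    spouse = new_id()
                    spouse_sex = 2 if sex == 1 else 1
                    individuals.append(Individual(spouse, fid, None, None, spouse_sex))
                    if sex == 1:
                        next_couples.append((child, spouse))
                    else:
                        next_couples.append((spouse, child))
            couples = next_couples
    return Pedigree(individuals)


def gene_drop_genotypes(
    ped: Pedigree,
    mafs: np.ndarray,
    seed: int | np.random.Generator = 0,
    variants: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Drop founder alleles through the pedigree, independently per site.

    Founder alleles are Bernoulli(MAF); each child allele is drawn uniformly
    from the transmitting parent's two alleles.  ``variants`` metadata is
    synthesized (chrom "1", positions 10 apart) when not supplied.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs < 0) | (mafs > 0.5)):
        raise ParameterError("founder MAFs must lie in [0, 0.5]")
    m = len(mafs)
    order = ped.topological_order
    pos = {iid: i for i, iid in enumerate(order)}
    n = len(order)
    alleles = np.zeros((n, 2, m), dtype=np.uint8)
    founder_rows = [pos[ind.iid] for ind in ped.founders()]
    alleles[founder_rows] = rng.random((len(founder_rows), 2, m)) < mafs
    cols = np.arange(m)
    for ind in ped.individuals:
        if ind.father is None:
            continue
        # topological order guarantees parents are already filled
        i = pos[ind.iid]
        for slot, parent in enumerate((ind.father, ind.mother)):
            pick = rng.integers(0, 2, size=m)
            alleles[i, slot] = alleles[pos[parent], pick, cols]
    G = alleles.sum(axis=1, dtype=np.int16).astype(float)
    perm = np.array([pos[iid] for iid in ped.sample_ids])
    if variants is None:
        variants = pd.DataFrame(
            {
                "chrom": "1",
                "pos": 10 * (np.arange(m) + 1),
                "ref": "A",
                "alt": "C",
            }
        )
    return GenotypeMatrix(ped.sample_ids, variants.reset_index(drop=True), G[perm])


def draw_variance_explained(
    cfg: SimulationConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-causal-SNV liability variance explained.

    Gamma with the configured mean and SD, resampled above
    ``causal_variance_max`` so the support is (0, max].
    """
    if n == 0:
        return np.zeros(0)
    if cfg.causal_variance_sd == 0:
        return np.full(n, cfg.causal_variance_mean)
    shape = (cfg.causal_variance_mean / cfg.causal_variance_sd) ** 2
    scale = cfg.causal_variance_sd**2 / cfg.causal_variance_mean
    out = rng.gamma(shape, scale, size=n)
    for _ in range(100):
        over = out > cfg.causal_variance_max
        if not over.any():
            break
        out[over] = rng.gamma(shape, scale, size=int(over.sum()))
    return np.minimum(out, cfg.causal_variance_max)


def simulate_phenotype(
    ped: Pedigree,
    gm: GenotypeMatrix,
    cfg: SimulationConfig,
    variance_explained: np.ndarray | None = None,
    mafs: np.ndarray | None = None,
    kinship: KinshipMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> PhenotypeVector:
    """Liability-threshold binary phenotype with a polygenic pedigree term.

    ``variance_explained`` gives each variant's target share v_j of liability
    variance (zero for non-causal variants); the allelic effect is
    beta_j = sqrt(v_j / (2 p_j (1 - p_j))) with p_j the founder MAF.  The
    residual absorbs 1 - h2 - sum(v) so total liability variance is 1.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    n = len(ped)
    if variance_explained is None:
        variance_explained = np.zeros(gm.n_variants)
    v = np.asarray(variance_explained, dtype=float)
    if np.any(v < 0):
        raise ParameterError("variance explained must be >= 0")
    budget = cfg.polygenic_heritability + v.sum()
    if budget >= 1.0:
        raise ParameterError(
            f"variance budget {budget:.3f} >= 1 (heritability + causal effects)"
        )
    genetic = np.zeros(n)
    causal = np.flatnonzero(v > 0)
    if len(causal):
        if mafs is None:
            G_causal = gm.G[:, causal]
            called = np.sum(~np.isnan(G_causal), axis=0)
            p = np.nansum(G_causal, axis=0) / (2.0 * called)
        else:
            p = np.asarray(mafs, dtype=float)[causal]
        p = np.clip(p, 1e-12, 1 - 1e-12)
        beta = np.sqrt(v[causal] / (2.0 * p * (1.0 - p)))
        G_causal = np.nan_to_num(gm.G[:, causal], nan=0.0)
        genetic = (G_causal - 2.0 * p) @ beta
    if cfg.polygenic_heritability > 0:
        if kinship is None:
            kinship = theoretical_kinship(ped)
        K = kinship.subset(ped.sample_ids).k
        try:
            L = np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            w, Q = np.linalg.eigh(K)
            L = Q * np.sqrt(np.maximum(w, 0.0))
        a = np.sqrt(cfg.polygenic_heritability) * (L @ rng.standard_normal(n))
    else:
        a = np.zeros(n)
    e = np.sqrt(1.0 - budget) * rng.standard_normal(n)
    liability = genetic + a + e
    threshold = stats.norm.isf(cfg.prevalence)
    return PhenotypeVector(ped.sample_ids, (liability > threshold).astype(int))


def label_causal_genes(
    genesets: list[GeneSet], variance_explained: np.ndarray
) -> list[GeneSet]:
    """Flag each gene causal iff >= 1 member SNV has positive effect."""
    v = np.asarray(variance_explained, dtype=float)
    return [
        replace_flag(g, bool(np.any(v[g.variant_indices] > 0))) for g in genesets
    ]


def replace_flag(g: GeneSet, flag: bool) -> GeneSet:
    return GeneSet(
        gene_name=g.gene_name,
        chrom=g.chrom,
        start=g.start,
        end=g.end,
        variant_indices=g.variant_indices,
        causal_flag=flag,
    )


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Run the full generator: pedigree, gene catalogue, genotypes, phenotype.

    Genes are laid consecutively on chromosome 1 (variants 10 bp apart,
    1 kb between genes); per-gene SNV counts are uniform over
    ``snvs_per_gene_range`` and founder MAFs log-uniform over ``maf_range``.
    A ``causal_fraction`` of genes receives exactly one causal SNV whose
    variance explained follows the configured spectrum.  Per-stage random
    streams are derived from the master seed so each stage is independently
    reproducible.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_ped, rng_gene, rng_drop, rng_phen = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    ped = simulate_pedigrees(cfg, rng_ped)
    kin = theoretical_kinship(ped)

    lo_s, hi_s = cfg.snvs_per_gene_range
    sizes = rng_gene.integers(lo_s, hi_s + 1, size=cfg.n_genes)
    lo_m, hi_m = cfg.maf_range
    mafs = np.exp(
        rng_gene.uniform(np.log(lo_m), np.log(hi_m), size=int(sizes.sum()))
    )

    gene_rows = []
    genesets: list[GeneSet] = []
    positions = np.empty(int(sizes.sum()), dtype=int)
    cursor = 1000
    offset = 0
    for i, size in enumerate(sizes):
        idx = np.arange(offset, offset + size)
        pos = cursor + 10 * np.arange(size)
        positions[idx] = pos
        name = f"GENE{i + 1:05d}"
        gene_rows.append(("1", int(pos[0]), int(pos[-1]), name))
        genesets.append(
            GeneSet(
                gene_name=name,
                chrom="1",
                start=int(pos[0]),
                end=int(pos[-1]),
                variant_indices=idx,
            )
        )
        cursor = int(pos[-1]) + 1000
        offset += size
    gene_table = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene"])

    n_causal = int(round(cfg.causal_fraction * cfg.n_genes))
    v = np.zeros(int(sizes.sum()))
    if n_causal:
        causal_genes = rng_gene.choice(cfg.n_genes, size=n_causal, replace=False)
        effects = draw_variance_explained(cfg, n_causal, rng_gene)
        for g_idx, effect in zip(causal_genes, effects):
            snv = rng_gene.choice(genesets[g_idx].variant_indices)
            v[snv] = effect
    genesets = label_causal_genes(genesets, v)

    variants = pd.DataFrame(
        {"chrom": "1", "pos": positions, "ref": "A", "alt": "C"}
    )
    gm = gene_drop_genotypes(ped, mafs, rng_drop, variants=variants)
    y = simulate_phenotype(
        ped, gm, cfg, variance_explained=v, mafs=mafs, kinship=kin, rng=rng_phen
    )
    return StudyData(
        config=cfg,
        pedigree=ped,
        genotypes=gm,
        genesets=genesets,
        gene_table=gene_table,
        phenotype=y,
        kinship=kin,
        variance_explained=v,
    )


# ---------------------------------------------------------------------------
# plain-text writers


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write genotypes as an uncompressed VCF (GT only)."""
    geno_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.variants["chrom"].astype(str)):
            sub = gm.variants[gm.variants["chrom"].astype(str) == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_variants):
            row = gm.variants.iloc[j]
            calls = [
                "./." if np.isnan(g) else geno_code[float(g)] for g in gm.G[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\tv{j + 1}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_fam(ped: Pedigree, path, phenotype: PhenotypeVector | None = None) -> None:
    """Write a PLINK FAM file; affection coded 1/2, -9 when unknown."""
    status = {}
    if phenotype is not None:
        status = dict(zip(phenotype.sample_ids, phenotype.y))
    with open(path, "w") as fh:
        for ind in ped.individuals:
            pheno = status.get(ind.iid)
            code = "-9" if pheno is None else str(int(pheno) + 1)
            fh.write(
                f"{ind.fid}\t{ind.iid}\t{ind.father or '0'}\t"
                f"{ind.mother or '0'}\t{ind.sex}\t{code}\n"
            )


def write_phenotype_waves(
    phenotype: PhenotypeVector,
    path,
    n_waves: int = 4,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> None:
    """Write a longitudinal phenotype TSV by replicating the binary status
    across waves with independent per-wave missingness ('NA')."""
    if rng is None:
        rng = np.random.default_rng(0)
    with open(path, "w") as fh:
        fh.write("iid\t" + "\t".join(f"wave{w + 1}" for w in range(n_waves)) + "\n")
        for iid, status in zip(phenotype.sample_ids, phenotype.y):
            cells = [
                "NA" if rng.random() < missing_rate else str(int(status))
                for _ in range(n_waves)
            ]
            fh.write(iid + "\t" + "\t".join(cells) + "\n")


def write_gene_table(gene_table: pd.DataFrame, path) -> None:
    gene_table.to_csv(path, sep="\t", header=False, index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
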