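"""Genotype input, phenotype collapsing, and gene-set construction.

Genotypes are held as an individuals x variants matrix of additive
minor-allele counts (0/1/2, NaN for missing).  Variants are mapped to genes
by 1-based inclusive start-stop containment, and genes are filtered to a size
window (default 2-200 SNVs) before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Additive minor-allele counts with per-variant metadata.

    ``variants`` is a DataFrame with columns (chrom, pos, ref, alt); ``G`` is
    float with entries in {0, 1, 2, NaN}.  Column j of ``G`` corresponds to
    row j of ``variants``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (len(self.sample_ids), len(self.variants)):
            raise FormatError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.G < 0) | (self.G > 2)
        if np.any(bad):
            raise ValidationError("genotype counts outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(list(ids), self.variants, self.G[rows, :])


@dataclass
class GeneSet:
    """A gene with the indices of its member variants in a GenotypeMatrix."""

    gene_name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    variant_indices: np.ndarray
    causal_flag: bool = False  # used only by the evaluation stratification

    @property
    def n_variants(self) -> int:
        return len(self.variant_indices)


@dataclass
class PhenotypeVector:
    """Binary ever-affected status; all-missing individuals are excluded."""

    sample_ids: list[str]
    y: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if self.y.shape != (len(self.sample_ids),):
            raise FormatError("phenotype length does not match sample ids")
        if not np.isin(self.y, [0, 1]).all():
            raise ValidationError("phenotype entries must be 0 or 1")

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return int((self.y == 0).sum())


def read_genotypes(path) -> GenotypeMatrix:
    """Read a VCF into minor-allele additive coding.

    Biallelic records only; multi-allelic records are skipped with a warning.
    If the ALT allele frequency exceeds 0.5 the coding is flipped so counts
    measure the minor allele.  Missing GT becomes NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF contains zero samples")
    rows = []
    meta = []
    n_skipped = 0
    for record in vcf:
        if len(record.ALT) != 1:
            n_skipped += 1
            continue
        gt = record.gt_types.astype(float)  # 0/1/2 alt copies, 3 = missing
        gt[gt == 3] = np.nan
        if np.all(np.isnan(gt)):
            alt_count = 0.0
        else:
            alt_count = np.nansum(gt)
        n_called = np.sum(~np.isnan(gt))
        flipped = False
        if n_called > 0 and alt_count / (2 * n_called) > 0.5:
            gt = 2.0 - gt
            flipped = True
        rows.append(gt)
        meta.append(
            {
                "chrom": record.CHROM,
                "pos": record.POS,
                "ref": record.REF,
                "alt": record.ALT[0],
                "flipped": flipped,
            }
        )
    if n_skipped:
        logger.warning("%s: skipped %d multi-allelic records", path, n_skipped)
    if not rows:
        raise FormatError(f"{path}: no usable biallelic records")
    variants = pd.DataFrame(meta)
    G = np.asarray(rows).T  # samples x variants
    return GenotypeMatrix(samples, variants, G)


def collapse_phenotype(waves: pd.DataFrame, id_column: str | None = None) -> PhenotypeVector:
    """Collapse up to 4 longitudinal binary statuses to ever-affected.

    ``waves``: one row per individual; the id column (first column by
    default) plus >=1 wave columns with entries in {0, 1, NA}.  y = 1 if any
    non-missing wave is 1; y = 0 if all non-missing waves are 0; individuals
    with every wave missing are excluded (listed in ``excluded``).
    """
    if id_column is None:
        id_column = waves.columns[0]
    wave_cols = [c for c in waves.columns if c != id_column]
    if not wave_cols:
        raise ValidationError("phenotype table has no wave columns")
    values = waves[wave_cols].to_numpy(dtype=float)
    valid = ~np.isnan(values)
    if not np.isin(values[valid], [0.0, 1.0]).all():
        raise ValidationError("wave statuses must be 0, 1 or missing")
    any_case = np.nansum(np.where(valid, values, 0.0), axis=1) > 0
    any_observed = valid.any(axis=1)
    ids = waves[id_column].astype(str).tolist()
    keep = [i for i, ok in enumerate(any_observed) if ok]
    excluded = [ids[i] for i, ok in enumerate(any_observed) if not ok]
    if excluded:
        logger.info("excluded %d individuals with all waves missing", len(excluded))
    return PhenotypeVector(
        [ids[i] for i in keep], any_case[keep].astype(int), excluded
    )


def read_phenotype(path) -> PhenotypeVector:
    """Read a phenotype TSV (id + wave columns, 'NA' missing) and collapse it."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return collapse_phenotype(df)


def read_gene_table(path) -> pd.DataFrame:
    """Read a 4-column gene TSV (chrom, start, end, gene), 1-based inclusive."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str},
        comment="#",
    )
    bad = df[df["start"] > df["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"{path}: gene {row['gene']!r} has start {row['start']} > end {row['end']}"
        )
    return df


def map_variants_to_genes(gm: GenotypeMatrix, genes: pd.DataFrame) -> list[GeneSet]:
    """Assign each variant to every gene whose interval contains its position.

    Containment is 1-based inclusive on both ends; overlapping genes are
    allowed, so a variant may join several gene sets.  Genes with zero mapped
    variants are dropped.  Output order follows the gene table.
    """
    bad = genes[genes["start"] > genes["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"gene {row['gene']!r} has start {row['start']} > end {row['end']}"
        )
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        tree = IntervalTree()
        for row_idx, row in sub.iterrows():
            # intervaltree is half-open; +1 makes `end` inclusive.
            tree.addi(int(row["start"]), int(row["end"]) + 1, row_idx)
        trees[str(chrom)] = tree
    members: dict[int, list[int]] = {i: [] for i in genes.index}
    chroms = gm.variants["chrom"].astype(str).to_numpy()
    positions = gm.variants["pos"].to_numpy()
    for v_idx in range(gm.n_variants):
        tree = trees.get(chroms[v_idx])
        if tree is None:
            continue
        for hit in tree.at(int(positions[v_idx])):
            members[hit.data].append(v_idx)
    out = []
    for row_idx, row in genes.iterrows():
        idx = members[row_idx]
        if not idx:
            continue
        out.append(
            GeneSet(
                gene_name=str(row["gene"]),
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                variant_indices=np.array(sorted(idx), dtype=int),
            )
        )
    return out


def filter_genes_by_size(
    genesets: list[GeneSet], min_snvs: int = 2, max_snvs: int = 200
) -> list[GeneSet]:
    """Keep genes with min_snvs <= #variants <= max_snvs (bounds inclusive)."""
    if min_snvs < 1 or max_snvs < min_snvs:
        raise ParameterError(
            f"invalid gene-size bounds: min={min_snvs}, max={max_snvs}"
        )
    return [g for g in genesets if min_snvs <= g.n_variants <= max_snvs]


def compute_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor allele frequency, folded to <= 0.5.

    MAF = sum(counts) / (2 * n_nonmissing); all-missing variants get NaN and
    a warning (they should be excluded from gene sets).
    """
    n_called = np.sum(~np.isnan(gm.G), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(gm.G, axis=0) / (2.0 * n_called)
    freq = np.where(n_called == 0, np.nan, freq)
    if np.any(n_called == 0):
        logger.warning(
            "%d variants have no called genotypes (MAF = NaN)",
            int(np.sum(n_called == 0)),
        )
    return np.minimum(freq, 1.0 - freq)


def mean_impute(G: np.ndarray) -> np.ndarray:
    """Replace missing entries with the per-variant mean count."""
    if not np.isnan(G).any():
        return G
    out = G.copy()
    col_mean = np.nanmean(out, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out
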