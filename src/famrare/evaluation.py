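"""Study orchestration: run all tests per gene, tabulate type I error and
power by causal stratum, cross-method p-value correlations, and the
Bonferroni screen used for real-data reporting."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InsufficientDataError, ValidationError
from .family_tests import chi2min_test, cmc_test, compute_pcorr, t2_test
from .genotype_geneset import GeneSet, GenotypeMatrix, PhenotypeVector, compute_maf
from .pedigree_kinship import KinshipMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene",
    "method",
    "maf_threshold",
    "kinship_mode",
    "statistic",
    "df",
    "p_value",
    "n_variants",
    "flags",
]


def _method_label(method: str, threshold: float | None) -> str:
    if method == "CMC" and threshold is not None:
        return f"CMC_{threshold * 100:g}%"
    return method


def run_study(
    genesets: list[GeneSet],
    gm: GenotypeMatrix,
    y: PhenotypeVector,
    kinships: dict[str, KinshipMatrix],
    methods: tuple[str, ...] = ("T2", "CMC", "CHI2MIN"),
    cmc_thresholds: tuple[float, ...] = (0.05, 0.005),
    log_every: int = 500,
) -> pd.DataFrame:
    """Apply every requested test to every gene under each kinship mode.

    Returns one row per (gene x method[x threshold] x kinship mode);
    untestable genes are kept with a flag rather than dropped.  MAF is
    computed once on the full phenotyped analysis sample.  Deterministic
    given its inputs.
    """
    unknown = set(methods) - {"T2", "CMC", "CHI2MIN"}
    if unknown:
        raise ValidationError(f"unknown methods: {sorted(unknown)}")
    missing = [s for s in y.sample_ids if s not in set(gm.sample_ids)]
    for mode, kin in kinships.items():
        missing += [
            s for s in y.sample_ids if s not in set(kin.sample_ids)
        ]
    if missing:
        raise AlignmentError(
            f"samples phenotyped but absent from genotypes/kinship: "
            f"{sorted(set(missing))[:10]}"
        )
    gm_aligned = gm.subset_samples(y.sample_ids)
    maf = compute_maf(gm_aligned)
    pcorrs = {mode: compute_pcorr(kin, y) for mode, kin in kinships.items()}
    rows = []
    for n_done, gene in enumerate(genesets, start=1):
        idx = gene.variant_indices
        usable = idx[~np.isnan(maf[idx])]
        G_gene = gm_aligned.G[:, usable]
        gene_maf = maf[usable]
        for mode in kinships:
            pcorr = pcorrs[mode]
            for method in methods:
                if method == "T2":
                    results = [
                        t2_test(
                            G_gene, y, kinships[mode],
                            gene_name=gene.gene_name, kinship_mode=mode,
                            pcorr=pcorr,
                        )
                    ]
                elif method == "CMC":
                    results = [
                        cmc_test(
                            G_gene, y, kinships[mode], gene_maf, thr,
                            gene_name=gene.gene_name, kinship_mode=mode,
                            pcorr=pcorr,
                        )
                        for thr in cmc_thresholds
                    ]
                else:
                    results = [
                        chi2min_test(
                            G_gene, y, kinships[mode],
                            gene_name=gene.gene_name, kinship_mode=mode,
                            pcorr=pcorr,
                        )
                    ]
                for res in results:
                    rows.append(
                        (
                            res.gene_name,
                            _method_label(res.method, res.maf_threshold),
                            res.maf_threshold,
                            res.kinship_mode,
                            res.statistic,
                            res.df,
                            res.p_value,
                            res.n_variants,
                            res.flags,
                        )
                    )
        if log_every and n_done % log_every == 0:
            logger.info("tested %d / %d genes", n_done, len(genesets))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def summarize_type1_power(
    results: pd.DataFrame, truth: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Fraction of genes significant at ``alpha``, stratified by method,
    kinship mode and causal status (the type-I-error / power table)."""
    truth_map = dict(
        zip(truth["gene"].astype(str), truth["causal_flag"].astype(int))
    )
    missing = set(results["gene"].astype(str)) - set(truth_map)
    if missing:
        raise ValidationError(
            f"genes in results missing from truth: {sorted(missing)[:10]}"
        )
    df = results.copy()
    df["stratum"] = (
        df["gene"].astype(str).map(truth_map).map({1: "causal", 0: "noncausal"})
    )
    out = []
    grouped = df.groupby(["method", "kinship_mode", "stratum"], sort=False)
    for (method, mode, stratum), sub in grouped:
        n_genes = len(sub)
        n_sig = int((sub["p_value"] < alpha).sum())
        out.append(
            {
                "method": method,
                "kinship_mode": mode,
                "stratum": stratum,
                "n_genes": n_genes,
                "n_significant": n_sig,
                "proportion_significant": n_sig / n_genes,
            }
        )
    return pd.DataFrame(out)


def pvalue_correlations(results: pd.DataFrame) -> pd.DataFrame:
    """Pearson and Spearman correlations between p-value vectors of every
    pair of (method, kinship mode) runs, aligned on genes, listwise-complete.
    """
    wide = results.pivot_table(
        index="gene",
        columns=["method", "kinship_mode"],
        values="p_value",
        aggfunc="first",
    )
    wide = wide.dropna(axis=0, how="any")
    if len(wide) < 3:
        raise InsufficientDataError(
            f"only {len(wide)} genes with complete p-values; need >= 3"
        )
    cols = list(wide.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            pa, pb = wide[a].to_numpy(), wide[b].to_numpy()
            rows.append(
                {
                    "method_1": a[0],
                    "kinship_1": a[1],
                    "method_2": b[0],
                    "kinship_2": b[1],
                    "pearson": float(stats.pearsonr(pa, pb)[0]),
                    "spearman": float(stats.spearmanr(pa, pb)[0]),
                    "n_genes": len(wide),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ScreenReport:
    threshold: float  # exact alpha / n_genes, no premature rounding
    significant: pd.DataFrame  # genes below the Bonferroni threshold
    top: pd.DataFrame  # smallest p-values per method regardless of cutoff


def bonferroni_screen(
    results: pd.DataFrame,
    alpha: float = 0.05,
    n_genes: int | None = None,
    top_p: float = 1e-4,
    top_k: int = 5,
) -> ScreenReport:
    """Bonferroni screen across genes plus a top-gene report.

    ``threshold`` is the exact rational alpha / n_genes; ``top`` lists, per
    method x kinship mode, the ``top_k`` smallest p-values annotated with
    whether they fall below ``top_p`` (the suggestive-reporting cutoff).
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0,1): {alpha}")
    if n_genes is None:
        n_genes = results["gene"].nunique()
    if n_genes < 1:
        raise ValidationError("need at least one gene")
    threshold = alpha / n_genes
    significant = (
        results[results["p_value"] < threshold]
        .sort_values("p_value")
        .reset_index(drop=True)
    )
    top = (
        results.sort_values("p_value")
        .groupby(["method", "kinship_mode"], sort=False)
        .head(top_k)
        .sort_values(["method", "kinship_mode", "p_value"])
        .reset_index(drop=True)
    )
    top["suggestive"] = top["p_value"] < top_p
    return ScreenReport(threshold=threshold, significant=significant, top=top)
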