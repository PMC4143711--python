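"""Gene-level association tests for binary traits in pedigrees.

Three tests, all corrected for pedigree correlation through a scalar factor
P_corr built from K = 2 * Phi (twice the kinship matrix):

* generalized T2 — a Hotelling-style multivariate comparison of mean
  minor-allele counts between cases and controls across the gene's t
  variants; T2 / P_corr is chi-squared with t degrees of freedom under the
  null (additive polygenic inheritance).
* CMC — variants with MAF below a threshold are collapsed into one carrier
  indicator ("super variant") before the same T2 machinery.
* chi2-min — the minimum single-marker p-value in the gene (Pearson or
  Fisher on the 2x2 allele-count table, P_corr-adjusted), deliberately NOT
  corrected for the number of variants, so its type I error is inflated by
  construction.

P_corr is the variance-inflation ratio of the case-control mean contrast
under genotype correlation K relative to independence:

    c_i = 1/n_A (case) or -1/n_G (control)
    P_corr = (c' K c) / (1/n_A + 1/n_G)

so identity kinship (unrelated samples) gives P_corr = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, ParameterError, ValidationError
from .genotype_geneset import PhenotypeVector, mean_impute
from .pedigree_kinship import KinshipMatrix

EXPECTED_COUNT_RULE = 5.0  # all expected cells >= 5 -> Pearson, else Fisher


@dataclass(frozen=True)
class TestResult:
    gene_name: str
    method: str  # T2 | CMC | CHI2MIN
    kinship_mode: str  # theoretical | estimated | identity | custom
    statistic: float
    df: int
    p_value: float
    n_variants: int
    maf_threshold: float | None = None  # CMC only
    flags: str = ""


def compute_pcorr(kin: KinshipMatrix, y: PhenotypeVector) -> float:
    """Pedigree correction factor for the case-control contrast.

    Requires at least one case and one control; the kinship matrix must
    cover every phenotyped sample (it is subset and aligned to ``y``).
    """
    n_a, n_g = y.n_cases, y.n_controls
    if n_a == 0 or n_g == 0:
        raise DegenerateDesignError(
            f"need both classes: {n_a} cases, {n_g} controls"
        )
    k = kin.subset(y.sample_ids).k
    c = np.where(y.y == 1, 1.0 / n_a, -1.0 / n_g)
    value = float(c @ k @ c) / (1.0 / n_a + 1.0 / n_g)
    if value <= 0:
        raise ValidationError(f"P_corr = {value:.3g} is not positive; K invalid")
    return value


def _pooled_covariance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled within-group covariance, denominator n - 2."""
    n = X.shape[0]
    Xa = X[y == 1]
    Xg = X[y == 0]
    da = Xa - Xa.mean(axis=0)
    dg = Xg - Xg.mean(axis=0)
    return (da.T @ da + dg.T @ dg) / (n - 2)


def _t2_core(
    X: np.ndarray,
    y: np.ndarray,
    pcorr: float,
) -> tuple[float, int, str]:
    """T2 / P_corr statistic, df, flags on an imputed genotype submatrix."""
    keep = X.std(axis=0) > 0
    flags = ""
    if not keep.all():
        flags = f"dropped_{int((~keep).sum())}_zero_variance"
        X = X[:, keep]
    if X.shape[1] == 0:
        return 0.0, 0, (flags + ";untestable").lstrip(";")
    n_a = int((y == 1).sum())
    n_g = int((y == 0).sum())
    d = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
    S = _pooled_covariance(X, y) * (1.0 / n_a + 1.0 / n_g)
    rank = int(np.linalg.matrix_rank(S))
    if rank < S.shape[0]:
        flags = (flags + ";rank_deficient").lstrip(";")
        S_inv = np.linalg.pinv(S)
    else:
        S_inv = np.linalg.inv(S)
    t2 = float(d @ S_inv @ d)
    return t2 / pcorr, rank, flags


def t2_test(
    G_gene: np.ndarray,
    y: PhenotypeVector,
    kin: KinshipMatrix,
    gene_name: str = "",
    kinship_mode: str = "custom",
    pcorr: float | None = None,
) -> TestResult:
    """Generalized T2 test on a gene's genotype submatrix.

    Rows of ``G_gene`` follow ``y.sample_ids``.  Zero-variance variants are
    dropped; a rank-deficient pooled covariance is pseudo-inverted with
    df = rank.  A gene with no testable variant returns p = 1, df = 0,
    flagged 'untestable'.
    """
    if pcorr is None:
        pcorr = compute_pcorr(kin, y)
    X = mean_impute(np.atleast_2d(np.asarray(G_gene, dtype=float)))
    stat, df, flags = _t2_core(X, y.y, pcorr)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return TestResult(
        gene_name=gene_name,
        method="T2",
        kinship_mode=kinship_mode,
        statistic=stat,
        df=df,
        p_value=p,
        n_variants=G_gene.shape[1],
        flags=flags,
    )


def cmc_collapse(
    G_gene: np.ndarray, maf: np.ndarray, threshold: float
) -> np.ndarray:
    """Collapse variants with MAF < threshold into one carrier indicator.

    Columns at or above the threshold pass through unchanged (in order); if
    any column is rare, a single 0/1 super-variant column is appended that is
    1 for individuals carrying >=1 minor allele at any rare site.  With no
    rare column the output equals the input.  Missing entries count as
    non-carriers for the indicator.
    """
    if not (0.0 < threshold <= 0.5):
        raise ParameterError(f"MAF threshold must be in (0, 0.5], got {threshold}")
    maf = np.asarray(maf, dtype=float)
    if maf.shape != (G_gene.shape[1],):
        raise ValidationError("MAF vector length does not match gene columns")
    rare = maf < threshold
    if not rare.any():
        return G_gene
    with np.errstate(invalid="ignore"):
        carrier = np.nan_to_num(G_gene[:, rare], nan=0.0).sum(axis=1) > 0
    return np.column_stack([G_gene[:, ~rare], carrier.astype(float)])


def cmc_test(
    G_gene: np.ndarray,
    y: PhenotypeVector,
    kin: KinshipMatrix,
    maf: np.ndarray,
    threshold: float,
    gene_name: str = "",
    kinship_mode: str = "custom",
    pcorr: float | None = None,
) -> TestResult:
    """CMC test: T2 applied to the (partially) collapsed genotype matrix."""
    if pcorr is None:
        pcorr = compute_pcorr(kin, y)
    collapsed = cmc_collapse(np.asarray(G_gene, dtype=float), maf, threshold)
    X = mean_impute(collapsed)
    stat, df, flags = _t2_core(X, y.y, pcorr)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return TestResult(
        gene_name=gene_name,
        method="CMC",
        kinship_mode=kinship_mode,
        statistic=stat,
        df=df,
        p_value=p,
        n_variants=G_gene.shape[1],
        maf_threshold=threshold,
        flags=flags,
    )


def single_marker_test(
    g_variant: np.ndarray,
    y: PhenotypeVector,
    kin: KinshipMatrix | None = None,
    pcorr: float | None = None,
) -> float:
    """P_corr-adjusted single-marker p-value from the 2x2 allele-count table.

    The table crosses minor/major allele counts with case/control status.
    With all expected cells >= 5 the Pearson chi-squared (1 df, no continuity
    correction) is divided by P_corr; otherwise the two-sided Fisher exact p
    is mapped through the chi-squared(1) quantile, deflated by P_corr, and
    mapped back.  Monomorphic variants return p = 1.
    """
    if pcorr is None:
        if kin is None:
            raise ValidationError("need either a kinship matrix or pcorr")
        pcorr = compute_pcorr(kin, y)
    g = np.asarray(g_variant, dtype=float)
    called = ~np.isnan(g)
    case = (y.y == 1) & called
    ctrl = (y.y == 0) & called
    minor_case = float(g[case].sum())
    minor_ctrl = float(g[ctrl].sum())
    major_case = 2.0 * case.sum() - minor_case
    major_ctrl = 2.0 * ctrl.sum() - minor_ctrl
    table = np.array([[minor_case, major_case], [minor_ctrl, major_ctrl]])
    total = table.sum()
    if total == 0 or table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0  # monomorphic or one class absent at this site
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if expected.min() >= EXPECTED_COUNT_RULE:
        chi2 = float(((table - expected) ** 2 / expected).sum())
        return float(stats.chi2.sf(chi2 / pcorr, 1))
    p_fisher = float(stats.fisher_exact(np.rint(table).astype(int))[1])
    quantile = float(stats.chi2.isf(min(p_fisher, 1.0), 1))
    return float(stats.chi2.sf(quantile / pcorr, 1))


def chi2min_test(
    G_gene: np.ndarray,
    y: PhenotypeVector,
    kin: KinshipMatrix | None = None,
    gene_name: str = "",
    kinship_mode: str = "custom",
    pcorr: float | None = None,
) -> TestResult:
    """Minimum single-marker p-value in the gene, without multiplicity
    correction (anticonservative by design); df reported as 1.

    Ties for the minimum are resolved by recording every argmin column in the
    flags field.
    """
    if pcorr is None:
        if kin is None:
            raise ValidationError("need either a kinship matrix or pcorr")
        pcorr = compute_pcorr(kin, y)
    G = np.atleast_2d(np.asarray(G_gene, dtype=float))
    pvals = np.array(
        [single_marker_test(G[:, j], y, pcorr=pcorr) for j in range(G.shape[1])]
    )
    testable = ~np.isnan(pvals)
    if not testable.any():
        return TestResult(
            gene_name=gene_name,
            method="CHI2MIN",
            kinship_mode=kinship_mode,
            statistic=float("nan"),
            df=0,
            p_value=1.0,
            n_variants=G.shape[1],
            flags="untestable",
        )
    p_min = float(pvals[testable].min())
    argmin = np.flatnonzero(pvals == p_min)
    flags = "argmin=" + ",".join(map(str, argmin)) if len(argmin) > 1 else ""
    return TestResult(
        gene_name=gene_name,
        method="CHI2MIN",
        kinship_mode=kinship_mode,
        statistic=float(stats.chi2.isf(p_min, 1)),
        df=1,
        p_value=p_min,
        n_variants=G.shape[1],
        flags=flags,
    )
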