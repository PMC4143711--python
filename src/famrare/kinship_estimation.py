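"""Genotype-based kinship estimation.

Implements the robust between-family moment estimator built from
heterozygosity and opposite-homozygote counts.  For a pair (i, j), over the
sites called in both individuals:

    phi_hat = (N_AaAa - 2 * N_AAaa) / (N_Aa(i) + N_Aa(j))

where N_AaAa counts sites at which both are heterozygous, N_AAaa counts
opposite homozygotes, and N_Aa(i) counts heterozygous sites in individual i.
The estimator needs no allele frequencies and is invariant to allele-label
swaps.  The diagonal is fixed at 0.5 (no inbreeding estimation).
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ParameterError
from .genotype_geneset import GenotypeMatrix
from .pedigree_kinship import KinshipMatrix

logger = logging.getLogger(__name__)

RECOMMENDED_MIN_VARIANTS = 1000


def estimate_kinship(gm: GenotypeMatrix, clamp_negative: bool = False) -> KinshipMatrix:
    """Pairwise kinship from dense genotypes.

    Negative estimates are kept by default (unbiased for downstream quadratic
    forms); pass ``clamp_negative=True`` to floor them at 0.  Pairs with a
    zero heterozygosity denominator get NaN and are reported in a warning.
    """
    if gm.n_variants < RECOMMENDED_MIN_VARIANTS:
        logger.warning(
            "kinship estimation from only %d variants (>= %d recommended)",
            gm.n_variants,
            RECOMMENDED_MIN_VARIANTS,
        )
    G = gm.G
    valid = (~np.isnan(G)).astype(float)
    het = np.where(np.nan_to_num(G, nan=-1.0) == 1.0, 1.0, 0.0)
    hom_ref = np.where(np.nan_to_num(G, nan=-1.0) == 0.0, 1.0, 0.0)
    hom_alt = np.where(np.nan_to_num(G, nan=-1.0) == 2.0, 1.0, 0.0)

    n_het_het = het @ het.T
    n_opp_hom = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    # Heterozygous sites of i restricted to sites also called in j (and vice
    # versa), so missingness cannot bias the denominator.
    het_i = het @ valid.T
    denom = het_i + het_i.T

    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_het_het - 2.0 * n_opp_hom) / denom
    zero_denom = denom == 0
    np.fill_diagonal(zero_denom, False)
    if zero_denom.any():
        n_bad = int(zero_denom.sum() // 2)
        logger.warning(
            "%d pairs share no heterozygous called sites; kinship set to NaN", n_bad
        )
        phi[zero_denom] = np.nan
    if clamp_negative:
        phi = np.fmax(phi, 0.0)
    phi = 0.5 * (phi + phi.T)  # exact symmetry against float round-off
    np.fill_diagonal(phi, 0.5)
    return KinshipMatrix(list(gm.sample_ids), phi)


def subsample_variants(gm: GenotypeMatrix, n: int, seed: int) -> GenotypeMatrix:
    """Uniform random subset of n variants without replacement (seeded)."""
    if n <= 0:
        raise ParameterError(f"subsample size must be positive, got {n}")
    if n > gm.n_variants:
        raise ParameterError(
            f"requested {n} variants but only {gm.n_variants} available"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(gm.n_variants, size=n, replace=False))
    return GenotypeMatrix(
        list(gm.sample_ids),
        gm.variants.iloc[idx].reset_index(drop=True),
        gm.G[:, idx],
    )


def write_kinship_long(kin: KinshipMatrix, path) -> None:
    """Write kinship in long format (id1, id2, kinship), upper triangle."""
    import pandas as pd

    n = len(kin.sample_ids)
    iu = np.triu_indices(n)
    pd.DataFrame(
        {
            "id1": [kin.sample_ids[i] for i in iu[0]],
            "id2": [kin.sample_ids[j] for j in iu[1]],
            "kinship": kin.phi[iu],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
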