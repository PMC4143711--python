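import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from famrare import GenotypeMatrix, Individual, Pedigree

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

TRIO_FAM = """\
FAM1 DAD 0 0 1
FAM1 MOM 0 0 2
FAM1 KID DAD MOM 1
"""

# Three generations, 8 members: founder couple GF/GM, their children A and B,
# spouses SA/SB (founders), grandchildren C1 (of A) and C2 (of B) -> first
# cousins.  4 founders + 4 non-founders.
THREE_GEN_FAM = """\
F1 GF 0 0 1
F1 GM 0 0 2
F1 A GF GM 1
F1 SA 0 0 2
F1 B GF GM 2
F1 SB 0 0 1
F1 C1 A SA 1
F1 C2 SB B 2
"""

FIXTURE_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\tS5\tS6\tS7\tS8\tS9\tS10
1\t100\tv1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\t0/0\t0/0\t0/1\t0/0\t0/0\t0/0
1\t200\tv2\tG\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1\t1/1\t0/1\t1/1\t1/1\t1/1\t0/1\t1/1
1\t300\tv3\tC\tA,G\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0
1\t400\tv4\tT\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\t0/0\t0/0\t0/1\t0/0\t0/0\t0/0\t0/0
1\t500\tv5\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0
1\t600\tv6\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t1/1\t0/0\t0/1\t0/0\t0/0\t0/1\t0/0\t0/0
"""


@pytest.fixture
def trio_fam(tmp_path):
    path = tmp_path / "trio.fam"
    path.write_text(TRIO_FAM)
    return path


@pytest.fixture
def three_gen_fam(tmp_path):
    path = tmp_path / "three_gen.fam"
    path.write_text(THREE_GEN_FAM)
    return path


@pytest.fixture
def fixture_vcf(tmp_path):
    path = tmp_path / "fixture.vcf"
    path.write_text(FIXTURE_VCF)
    return path


def make_genotype_matrix(G, sample_ids=None, positions=None):
    """Wrap a raw count matrix in a GenotypeMatrix with synthetic metadata."""
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    if positions is None:
        positions = 10 * (np.arange(m) + 1)
    variants = pd.DataFrame(
        {"chrom": "1", "pos": positions, "ref": "A", "alt": "C"}
    )
    return GenotypeMatrix(list(sample_ids), variants, G)


def chain_pedigree(rows):
    """Build a Pedigree from (iid, father, mother, sex) tuples, family F1."""
    return Pedigree(
        [Individual(iid, "F1", f, m, sex) for iid, f, m, sex in rows]
    )


def mc_kinship(ped, n_reps, seed):
    """Monte-Carlo gene-dropping estimate of pairwise kinship.

    Founders carry unique allele labels; phi_hat(i, j) is the probability
    that an allele drawn from i matches one drawn from j, estimated over
    ``n_reps`` independent drops.  Returns (phi_hat, standard_error) arrays
    in pedigree sample order.  Independent of the recursive implementation.
    """
    rng = np.random.default_rng(seed)
    order = ped.topological_order
    pos = {iid: i for i, iid in enumerate(order)}
    n = len(order)
    alleles = np.zeros((n_reps, n, 2), dtype=np.int32)
    for i, iid in enumerate(order):
        ind = ped.get(iid)
        if ind.father is None:
            alleles[:, i, 0] = 2 * i
            alleles[:, i, 1] = 2 * i + 1
        else:
            for slot, parent in enumerate((ind.father, ind.mother)):
                pick = rng.integers(0, 2, size=n_reps)
                alleles[:, i, slot] = alleles[np.arange(n_reps), pos[parent], pick]
    phi = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                # P(two draws with replacement from i are IBD) = (1 + F)/2
                ibd = 0.5 * (
                    1.0 + (alleles[:, i, 0] == alleles[:, i, 1]).astype(float)
                )
            else:
                matches = sum(
                    (alleles[:, i, a] == alleles[:, j, b]).astype(float)
                    for a in range(2)
                    for b in range(2)
                )
                ibd = matches / 4.0
            phi[i, j] = phi[j, i] = ibd.mean()
            se[i, j] = se[j, i] = ibd.std(ddof=1) / np.sqrt(n_reps)
    perm = np.array([pos[iid] for iid in ped.sample_ids])
    return phi[np.ix_(perm, perm)], se[np.ix_(perm, perm)]
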