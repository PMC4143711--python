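"""Pedigree parsing and theoretical kinship.

The kinship coefficient phi(i, j) is the probability that an allele drawn at
random from individual i and one drawn from j at the same autosomal locus are
identical by descent.  For a pedigree with stated relationships it is computed
by the classical recursion over a topological ordering of the pedigree DAG:

    phi(i, i) = 1/2 * (1 + phi(father_i, mother_i))        (founders: 1/2)
    phi(i, j) = 1/2 * (phi(father_i, j) + phi(mother_i, j))   for j preceding i

Founders of different families (and co-founders within a family) are taken as
unrelated and non-inbred.  K = 2 * Phi is the additive genotype-correlation
matrix used by the association tests' P_corr correction.
"""

from __future__ import annotations

import graphlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, PedigreeError

logger = logging.getLogger(__name__)

MISSING_PARENT = "0"


@dataclass(frozen=True)
class Individual:
    iid: str
    fid: str
    father: str | None  # None for founders
    mother: str | None
    sex: int  # 1 male, 2 female, 0 unknown; carried but unused by kinship


@dataclass
class Pedigree:
    """A set of individuals with resolved parent links, grouped by family.

    Invariants (checked on construction): parent references resolve within
    the same family, the parent graph is acyclic, and every non-founder has
    exactly two recorded parents.
    """

    individuals: list[Individual]
    _index: dict[str, int] = field(init=False, repr=False)
    _topo: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {ind.iid: i for i, ind in enumerate(self.individuals)}
        if len(self._index) != len(self.individuals):
            dups = pd.Series([i.iid for i in self.individuals])
            dups = sorted(dups[dups.duplicated()].unique())
            raise PedigreeError(f"duplicate individual ids: {dups}")
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is None:
                    continue
                if parent not in self._index:
                    raise PedigreeError(
                        f"individual {ind.iid!r}: parent {parent!r} has no record"
                    )
                if self.individuals[self._index[parent]].fid != ind.fid:
                    raise PedigreeError(
                        f"individual {ind.iid!r}: parent {parent!r} belongs to a "
                        "different family"
                    )
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"individual {ind.iid!r} has exactly one recorded parent; "
                    "non-founders need both"
                )
        self._topo = self._topological_order()

    def _topological_order(self) -> list[str]:
        graph = {
            ind.iid: {p for p in (ind.father, ind.mother) if p is not None}
            for ind in self.individuals
        }
        try:
            return list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as exc:
            raise PedigreeError(f"pedigree contains a cycle: {exc.args[1]}") from exc

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def sample_ids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    @property
    def topological_order(self) -> list[str]:
        """Individual ids with every parent preceding its children."""
        return list(self._topo)

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.father is None]

    def nonfounders(self) -> list[Individual]:
        return [i for i in self.individuals if i.father is not None]

    def get(self, iid: str) -> Individual:
        return self.individuals[self._index[iid]]


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship coefficients phi over an ordered sample."""

    sample_ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.sample_ids)
        if self.phi.shape != (n, n):
            raise FormatError(
                f"kinship matrix shape {self.phi.shape} does not match "
                f"{n} sample ids"
            )
        if not np.allclose(self.phi, self.phi.T, atol=1e-8, equal_nan=True):
            raise FormatError("kinship matrix is not symmetric")

    @property
    def k(self) -> np.ndarray:
        """K = 2 * Phi, the additive genotype-correlation surrogate."""
        return 2.0 * self.phi

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            order = [index[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in kinship matrix") from exc
        return KinshipMatrix(list(ids), self.phi[np.ix_(order, order)])


def read_pedigree(path) -> Pedigree:
    """Read a PLINK FAM / linkage pedigree file.

    Expects >= 5 whitespace-delimited columns: family, individual, father,
    mother, sex[, phenotype ...]; "0" marks a missing parent.  An individual
    referenced as a parent but lacking its own row is materialized as a
    founder (logged).  A half-missing parent pair gets a phantom founder for
    the missing side (logged).
    """
    rows: list[tuple[str, str, str, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=5 columns, got {len(fields)}"
                )
            fid, iid, father, mother, sex = fields[:5]
            try:
                sex_code = int(sex)
            except ValueError:
                sex_code = 0
            rows.append((fid, iid, father, mother, sex_code))

    known = {iid for _, iid, _, _, _ in rows}
    phantom_counter = 0
    extra: list[Individual] = []
    individuals: list[Individual] = []
    for fid, iid, father, mother, sex in rows:
        father_id = None if father == MISSING_PARENT else father
        mother_id = None if mother == MISSING_PARENT else mother
        # Half-missing parent pair: materialize a phantom founder so that the
        # non-founder invariant (two parents) holds.
        if (father_id is None) != (mother_id is None):
            phantom_counter += 1
            phantom = f"_phantom{phantom_counter}"
            logger.warning(
                "individual %s has one recorded parent; adding phantom founder %s",
                iid,
                phantom,
            )
            extra.append(Individual(phantom, fid, None, None, 0))
            known.add(phantom)
            if father_id is None:
                father_id = phantom
            else:
                mother_id = phantom
        for parent, psex in ((father_id, 1), (mother_id, 2)):
            if parent is not None and parent not in known:
                logger.warning(
                    "parent %s of %s has no pedigree record; materialized as founder",
                    parent,
                    iid,
                )
                extra.append(Individual(parent, fid, None, None, psex))
                known.add(parent)
        individuals.append(Individual(iid, fid, father_id, mother_id, sex))
    return Pedigree(individuals + extra)


def theoretical_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix from stated relationships, founders unrelated/non-inbred.

    Individuals are processed in topological order so the recursion only ever
    touches completed entries; the returned matrix follows the pedigree's own
    sample order.
    """
    order = ped.topological_order
    pos = {iid: i for i, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for j, iid in enumerate(order):
        ind = ped.get(iid)
        if ind.father is None:
            phi[j, j] = 0.5
            continue
        f, m = pos[ind.father], pos[ind.mother]
        phi[j, j] = 0.5 * (1.0 + phi[f, m])
        row = 0.5 * (phi[f, :j] + phi[m, :j])
        phi[j, :j] = row
        phi[:j, j] = row
    # Reorder to the pedigree's sample order.
    perm = np.array([pos[iid] for iid in ped.sample_ids])
    return KinshipMatrix(ped.sample_ids, phi[np.ix_(perm, perm)])


def write_kinship(kin: KinshipMatrix, path) -> None:
    """Write a kinship matrix as a square TSV with id header row and column."""
    df = pd.DataFrame(kin.phi, index=kin.sample_ids, columns=kin.sample_ids)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def read_kinship(path) -> KinshipMatrix:
    """Read a square kinship TSV; validates squareness and symmetry."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed kinship TSV: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise FormatError(
            f"{path}: kinship matrix is not square ({df.shape[0]}x{df.shape[1]})"
        )
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError(f"{path}: row and column sample ids disagree")
    values = df.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-8, equal_nan=True):
        raise FormatError(f"{path}: kinship matrix is not symmetric")
    return KinshipMatrix([str(s) for s in df.index], values)
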