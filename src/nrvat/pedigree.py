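"""Pedigree representation, PED/FAM parsing and kinship machinery.

Families are the unit of dependence: every matrix downstream (relatedness
Psi, copula correlation Gamma, residual covariance) is block-diagonal over
families, with the row order fixed by order of appearance in the pedigree
file.  Kinship coefficients phi are computed by the standard recursive
algorithm over a founder-first topological order; the relatedness
(expected IBD-sharing) matrix is Psi = 2*phi, and the latent copula
correlation is Gamma = h2*Psi + (1-h2)*I.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Individual",
    "Family",
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "kinship_matrix",
    "relatedness",
    "copula_correlation",
]

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unresolved parent, cycle, inbreeding)."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Family:
    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError(f"family {self.family_id}: duplicate individual ids")
        idset = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in idset:
                    raise PedigreeError(
                        f"family {self.family_id}: parent {pid!r} of "
                        f"{m.individual_id!r} not found in family"
                    )
        self._topological_order()  # raises on cycles

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_founders(self) -> int:
        return sum(m.is_founder for m in self.members)

    def index_of(self) -> dict[str, int]:
        return {m.individual_id: j for j, m in enumerate(self.members)}

    def _topological_order(self) -> list[int]:
        """Founder-first order: every parent precedes its children."""
        idx = self.index_of()
        order: list[int] = []
        state = [0] * self.size  # 0 unseen, 1 in progress, 2 done

        def visit(j: int, stack: list[int]) -> None:
            if state[j] == 2:
                return
            if state[j] == 1:
                raise PedigreeError(
                    f"family {self.family_id}: cyclic ancestry involving "
                    f"{self.members[j].individual_id!r}"
                )
            state[j] = 1
            m = self.members[j]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(idx[pid], stack)
            state[j] = 2
            order.append(j)

        for j in range(self.size):
            visit(j, [])
        return order


@dataclass
class Pedigree:
    families: list[Family] = field(default_factory=list)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_individuals(self) -> int:
        return sum(f.size for f in self.families)

    @property
    def n_founders(self) -> int:
        return sum(f.n_founders for f in self.families)

    @property
    def n_nonfounders(self) -> int:
        return self.n_individuals - self.n_founders

    @property
    def family_sizes(self) -> np.ndarray:
        return np.array([f.size for f in self.families], dtype=int)

    def individual_keys(self) -> list[tuple[str, str]]:
        """(family_id, individual_id) pairs in global matrix row order."""
        return [
            (f.family_id, m.individual_id) for f in self.families for m in f.members
        ]

    def family_slices(self) -> list[slice]:
        out, ofs = [], 0
        for f in self.families:
            out.append(slice(ofs, ofs + f.size))
            ofs += f.size
        return out

    def relatedness_blocks(self) -> list[np.ndarray]:
        return [relatedness(f) for f in self.families]


def read_pedigree(path, dialect: str = "ped") -> Pedigree:
    """Read a whitespace-delimited PED/FAM file (FID IID PAT MAT SEX [extra...]).

    Parent code "0" means unknown (founder); both parent codes must be "0"
    together or resolve within the family.  Extra columns (phenotype,
    genotypes of a PED file) are ignored.
    """
    if dialect not in ("ped", "fam"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    rows: list[tuple[str, str, str, str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if len(tok) < 4:
                raise PedigreeError(f"{path}:{ln}: expected >=4 columns, got {len(tok)}")
            fid, iid, pat, mat = tok[:4]
            sex = tok[4] if len(tok) > 4 else "0"
            rows.append((fid, iid, pat, mat, sex))
    return _pedigree_from_rows(rows)


def _pedigree_from_rows(rows: Iterable[Sequence[str]]) -> Pedigree:
    by_family: dict[str, list[Individual]] = {}
    for fid, iid, pat, mat, sex in rows:
        # a half-known parent pair cannot be linked into the kinship recursion
        if (pat == "0") != (mat == "0"):
            raise PedigreeError(
                f"individual {iid!r} in family {fid!r} has exactly one known "
                "parent; both must be known or both '0'"
            )
        ind = Individual(
            individual_id=iid,
            father_id=None if pat == "0" else pat,
            mother_id=None if mat == "0" else mat,
            sex=_SEX_CODES.get(sex, "unknown"),
        )
        by_family.setdefault(fid, []).append(ind)
    return Pedigree([Family(fid, members) for fid, members in by_family.items()])


def write_pedigree(ped: Pedigree, path) -> None:
    """Write FAM-style records (FID IID PAT MAT SEX PHENO=-9)."""
    with open(path, "w") as fh:
        for fam in ped.families:
            for m in fam.members:
                fh.write(
                    f"{fam.family_id}\t{m.individual_id}\t{m.father_id or 0}\t"
                    f"{m.mother_id or 0}\t{_SEX_TO_CODE[m.sex]}\t-9\n"
                )


def kinship_matrix(family: Family) -> np.ndarray:
    """Kinship coefficients phi for one family by the recursive algorithm.

    phi(a, a) = 1/2 for non-inbred individuals; for a nonfounder a processed
    after b in founder-first order, phi(a, b) = [phi(father(a), b) +
    phi(mother(a), b)] / 2.  Founders of the same family are treated as
    mutually unrelated.  Pedigrees implying inbreeding (self-kinship > 1/2)
    are rejected: the copula correlation requires a unit diagonal.
    """
    n = family.size
    idx = family.index_of()
    phi = np.zeros((n, n))
    for j in family._topological_order():
        m = family.members[j]
        if m.is_founder:
            phi[j, j] = 0.5
            continue
        fa, mo = idx[m.father_id], idx[m.mother_id]
        if phi[fa, mo] > 0.0:
            raise PedigreeError(
                f"family {family.family_id}: parents of {m.individual_id!r} are "
                f"related (phi={phi[fa, mo]:.4g}); inbred pedigrees are not supported"
            )
        phi[j, j] = 0.5 + 0.5 * phi[fa, mo]
        for b in range(n):
            if b == j:
                continue
            val = 0.5 * (phi[fa, b] + phi[mo, b])
            # processed ancestors/relatives have their row final by topo order
            if phi[b, b] > 0.0:
                phi[j, b] = phi[b, j] = val
    return phi


def relatedness(family: Family) -> np.ndarray:
    """Expected IBD-sharing matrix Psi = 2 * phi (unit diagonal)."""
    psi = 2.0 * kinship_matrix(family)
    if not np.allclose(np.diag(psi), 1.0):
        raise PedigreeError(
            f"family {family.family_id}: self-relatedness differs from 1"
        )
    np.fill_diagonal(psi, 1.0)
    return psi


def copula_correlation(psi: np.ndarray, h2: float) -> np.ndarray:
    """Latent correlation Gamma = h2 * Psi + (1 - h2) * I.

    h2 is the polygenic heritability on the latent scale; valid range
    [0, 1) for modelling (h2 = 1 is allowed here for boundary checks).
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must lie in [0, 1); got {h2}")
    psi = np.asarray(psi, dtype=float)
    return h2 * psi + (1.0 - h2) * np.eye(psi.shape[0])
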