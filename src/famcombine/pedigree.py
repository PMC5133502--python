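"""Pedigree parsing and expected additive kinship.

The kinship coefficient phi(i, j) is the probability that an allele sampled
at random from individual i is identical by descent to one sampled from j.
Under a polygenic model the trait covariance between relatives is
sigma_g^2 * 2*phi(i, j), so the matrix handed to the linear mixed model is
the additive relationship matrix 2*Phi.

Kinship is computed by the standard recursion over a parent-ordered
pedigree (autosomal, sex ignored):

    phi(f, f)   = (1 + phi(father_f, mother_f)) / 2
    phi(f, j)   = (phi(father_f, j) + phi(mother_f, j)) / 2   for j earlier
    phi(founder, founder') = 0, phi(founder, founder) = 1/2

Missing parents contribute 0 (treated as unique, unrelated founders).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "kinship_matrix",
    "read_kinship",
    "write_kinship",
]


class PedigreeError(ValueError):
    """Structural or parse problem in a pedigree file."""


@dataclass
class Pedigree:
    """Family structure: individuals in file order plus parent links.

    ``parent_map`` maps each individual ID to ``(father, mother)`` where a
    missing parent is ``None``. Individuals referenced only as parents are
    not members; kinship computation adds them internally as founders.
    """

    individuals: list[str]
    parent_map: dict[str, tuple[str | None, str | None]]
    family_ids: dict[str, str]
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            dup = pd.Series(self.individuals)
            dup = dup[dup.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate individual ID {dup!r}")
        self._check_acyclic()

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for iid in self.individuals:
            seen.setdefault(self.family_ids[iid], None)
        return list(seen)

    def founders(self) -> list[str]:
        return [
            i
            for i in self.individuals
            if self.parent_map.get(i, (None, None)) == (None, None)
        ]

    def topological_order(self) -> list[str]:
        """All individuals (incl. parent-only placeholders), parents first."""
        members = set(self.individuals)
        everyone: dict[str, None] = {}
        for iid in self.individuals:
            f, m = self.parent_map.get(iid, (None, None))
            for p in (f, m):
                if p is not None and p not in members:
                    everyone.setdefault(p, None)
            everyone.setdefault(iid, None)
        parents = {
            i: tuple(p for p in self.parent_map.get(i, (None, None)) if p is not None)
            for i in everyone
        }
        children: dict[str, list[str]] = {i: [] for i in everyone}
        indeg: dict[str, int] = {}
        for i, ps in parents.items():
            indeg[i] = len(ps)
            for p in ps:
                children[p].append(i)
        ready = deque(i for i in everyone if indeg[i] == 0)
        order: list[str] = []
        while ready:
            i = ready.popleft()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(everyone):
            stuck = next(i for i in everyone if indeg[i] > 0)
            raise PedigreeError(f"parentage cycle involving individual {stuck!r}")
        return order

    def _check_acyclic(self) -> None:
        for iid, (f, m) in self.parent_map.items():
            if iid in (f, m):
                raise PedigreeError(f"individual {iid!r} is its own parent")
        self.topological_order()


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients aligned with ``sample_order``."""

    sample_order: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_order)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample_order")

    def relationship(self) -> np.ndarray:
        """Additive relationship matrix 2*Phi."""
        return 2.0 * self.values

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        pos = {iid: k for k, iid in enumerate(self.sample_order)}
        try:
            idx = np.array([pos[i] for i in ids])
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in kinship matrix") from None
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])


_SEX_CODES = {"1": "male", "2": "female"}


def read_pedigree(path, dialect: str = "ped") -> Pedigree:
    """Read a PED/FAM-style file (FID IID PAT MAT SEX [...]); "0" = missing.

    Extra columns (phenotype etc.) are ignored. File order is preserved.
    """
    if dialect not in ("ped", "fam"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    individuals: list[str] = []
    parent_map: dict[str, tuple[str | None, str | None]] = {}
    family_ids: dict[str, str] = {}
    sex: dict[str, str] = {}
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >= 5 columns, got {len(fields)}"
                )
            fid, iid, pat, mat, sx = fields[:5]
            if (fid, iid) in seen:
                raise PedigreeError(f"{path}:{lineno}: duplicate individual ({fid}, {iid})")
            seen.add((fid, iid))
            individuals.append(iid)
            parent_map[iid] = (None if pat == "0" else pat, None if mat == "0" else mat)
            family_ids[iid] = fid
            sex[iid] = _SEX_CODES.get(sx, "unknown")
    return Pedigree(individuals, parent_map, family_ids, sex)


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Expected kinship by the parent-ordered recursion, per family.

    Parent-only placeholders are included in the recursion as founders and
    dropped from the returned matrix (kinship coefficients are marginal, so
    this is plain subsetting). Between-family entries are exactly zero.
    """
    order = ped.topological_order()
    members = set(ped.individuals)
    # family label for placeholders: that of any child naming them
    fam_of: dict[str, str] = dict(ped.family_ids)
    for iid in ped.individuals:
        for p in ped.parent_map.get(iid, (None, None)):
            if p is not None and p not in fam_of:
                fam_of[p] = ped.family_ids[iid]

    by_family: dict[str, list[str]] = {}
    for i in order:
        by_family.setdefault(fam_of[i], []).append(i)

    n = ped.n
    pos = {iid: k for k, iid in enumerate(ped.individuals)}
    full = np.zeros((n, n))
    for fam_members in by_family.values():
        k = len(fam_members)
        local = {iid: j for j, iid in enumerate(fam_members)}
        phi = np.zeros((k, k))
        for j, iid in enumerate(fam_members):
            f, m = ped.parent_map.get(iid, (None, None))
            jf = local.get(f) if f is not None else None
            jm = local.get(m) if m is not None else None
            # off-diagonal with all earlier individuals, then the diagonal
            row = np.zeros(j)
            if jf is not None:
                row += phi[jf, :j]
            if jm is not None:
                row += phi[jm, :j]
            phi[j, :j] = phi[:j, j] = 0.5 * row
            phi[j, j] = 0.5 * (1.0 + (phi[jf, jm] if jf is not None and jm is not None else 0.0))
        keep = [j for j, iid in enumerate(fam_members) if iid in members]
        rows = [pos[fam_members[j]] for j in keep]
        full[np.ix_(rows, rows)] = phi[np.ix_(keep, keep)]
    return KinshipMatrix(list(ped.individuals), full)


def write_kinship(kin: KinshipMatrix, path) -> None:
    """Tab-delimited square matrix with a header row of IDs."""
    pd.DataFrame(kin.values, index=kin.sample_order, columns=kin.sample_order).to_csv(
        path, sep="\t", index_label="ID"
    )


def read_kinship(path) -> KinshipMatrix:
    """Read a user-supplied square kinship matrix (overrides the recursion)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("kinship file is not a square matrix with matching IDs")
    return KinshipMatrix(list(df.index), df.to_numpy(dtype=float))
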