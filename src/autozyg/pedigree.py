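"""Pedigree graphs, PED parsing, and expected identity by descent.

A :class:`Pedigree` is a directed family graph over :class:`Individual`
records (parent links, sex, affection status).  Consanguineous loops —
parents who share an ancestor, as in first-cousin matings — are explicitly
allowed; only ancestor *cycles* (an individual being its own ancestor) are
rejected.

Kinship is computed with the classic recursion over the pedigree: founders
are mutually unrelated, ``phi(i, i) = (1 + phi(father_i, mother_i)) / 2``,
and for ``i`` not an ancestor of ``j``,
``phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2``.  The expected
genome fraction shared IBD between two distinct individuals is reported as
``2 * phi`` (the outbred approximation; for inbred pairs this overstates
slightly because it ignores condensed identity states).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator


class PedigreeError(ValueError):
    """Invalid pedigree structure or lookup."""


class PedParseError(PedigreeError):
    """Malformed PED file."""


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def from_ped_code(cls, code: str) -> "Sex":
        return {"1": cls.MALE, "2": cls.FEMALE}.get(code, cls.UNKNOWN)

    def to_ped_code(self) -> str:
        return {Sex.MALE: "1", Sex.FEMALE: "2"}.get(self, "0")


class Phenotype(Enum):
    UNAFFECTED = "unaffected"
    AFFECTED = "affected"
    UNKNOWN = "unknown"

    @classmethod
    def from_ped_code(cls, code: str) -> "Phenotype":
        if code == "1":
            return cls.UNAFFECTED
        if code == "2":
            return cls.AFFECTED
        if code in ("0", "-9"):
            return cls.UNKNOWN
        raise PedParseError(f"unrecognised phenotype code {code!r}")

    def to_ped_code(self) -> str:
        return {Phenotype.UNAFFECTED: "1", Phenotype.AFFECTED: "2"}[self] \
            if self is not Phenotype.UNKNOWN else "0"


@dataclass(frozen=True)
class Individual:
    """One pedigree member.  Founders have neither parent."""

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def is_affected(self) -> bool:
        return self.phenotype is Phenotype.AFFECTED


class Pedigree:
    """A validated family graph with kinship/IBD expectations.

    Parameters
    ----------
    family_id
        Family identifier (the PED FID).
    members
        Individuals in file order.  Every referenced parent must itself be a
        member; an individual has either both parents or neither.
    """

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self._members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self._members:
                raise PedigreeError(
                    f"family {family_id}: duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        if not self._members:
            raise PedigreeError(f"family {family_id}: empty pedigree")
        self._validate()
        self._generation = self._generations()
        self._kin_cache: dict[tuple[str, str], float] = {}

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def member(self, individual_id: str) -> Individual:
        try:
            return self._members[individual_id]
        except KeyError:
            raise PedigreeError(
                f"family {self.family_id}: unknown individual {individual_id!r}"
            ) from None

    @property
    def members(self) -> list[Individual]:
        return list(self._members.values())

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self if m.is_founder]

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self if m.phenotype is Phenotype.AFFECTED]

    @property
    def unaffected(self) -> list[Individual]:
        return [m for m in self if m.phenotype is Phenotype.UNAFFECTED]

    def parents_of(self, individual_id: str) -> tuple[str, str] | None:
        ind = self.member(individual_id)
        if ind.is_founder:
            return None
        return ind.father_id, ind.mother_id  # type: ignore[return-value]

    def topological_order(self) -> list[Individual]:
        """Members sorted parents-before-children (stable within generation)."""
        return sorted(self, key=lambda m: self._generation[m.id])

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        for ind in self:
            half = (ind.father_id is None) != (ind.mother_id is None)
            if half:
                raise PedigreeError(
                    f"family {self.family_id}: individual {ind.id!r} has "
                    "exactly one parent; need both or neither")
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._members:
                    raise PedigreeError(
                        f"family {self.family_id}: parent {pid!r} of "
                        f"{ind.id!r} is not a pedigree member")
        if not any(m.is_founder for m in self):
            raise PedigreeError(f"family {self.family_id}: no founder")

    def _generations(self) -> dict[str, int]:
        gen: dict[str, int] = {}
        visiting: set[str] = set()

        def depth(iid: str) -> int:
            if iid in gen:
                return gen[iid]
            if iid in visiting:
                raise PedigreeError(
                    f"family {self.family_id}: ancestor cycle through {iid!r}")
            visiting.add(iid)
            ind = self._members[iid]
            g = 0 if ind.is_founder else 1 + max(
                depth(ind.father_id), depth(ind.mother_id))  # type: ignore[arg-type]
            visiting.discard(iid)
            gen[iid] = g
            return g

        for iid in self._members:
            depth(iid)
        return gen

    # -- kinship and IBD ----------------------------------------------------

    def kinship(self, i: str, j: str) -> float:
        """Kinship coefficient phi(i, j).

        The probability that one allele sampled from ``i`` and one from
        ``j`` at an autosomal locus are identical by descent.  Self-kinship
        is ``(1 + F_i) / 2`` where ``F_i`` is the inbreeding coefficient.
        """
        self.member(i), self.member(j)
        return self._kin(i, j)

    def inbreeding(self, i: str) -> float:
        """Inbreeding coefficient F = kinship of the parents (0 for founders)."""
        ind = self.member(i)
        if ind.is_founder:
            return 0.0
        return self._kin(ind.father_id, ind.mother_id)  # type: ignore[arg-type]

    def expected_ibd(self, i: str, j: str) -> float:
        """Expected genome fraction shared IBD between two distinct members.

        Returns ``2 * phi(i, j)`` — exact for outbred pairs (e.g. 0.5 for
        parent-offspring, 1/32 for second cousins), approximate for inbred
        pairs.  Capped at 1.
        """
        if i == j:
            raise PedigreeError("self IBD fraction is undefined; use inbreeding()")
        return min(1.0, 2.0 * self.kinship(i, j))

    def _kin(self, i: str, j: str) -> float:
        key = (i, j) if i <= j else (j, i)
        if key in self._kin_cache:
            return self._kin_cache[key]
        ind_i, ind_j = self._members[i], self._members[j]
        if i == j:
            v = 0.5 if ind_i.is_founder else 0.5 * (
                1.0 + self._kin(ind_i.father_id, ind_i.mother_id))  # type: ignore[arg-type]
        else:
            # Recurse on the later-generation member: it cannot be an
            # ancestor of the other, so the boundary condition is valid
            # even in looped (consanguineous) pedigrees.
            if self._generation[i] < self._generation[j]:
                ind_i, ind_j = ind_j, ind_i
            if ind_i.is_founder:
                v = 0.0  # two distinct founders (other is same generation 0)
            else:
                v = 0.5 * (self._kin(ind_i.father_id, ind_j.id) +  # type: ignore[arg-type]
                           self._kin(ind_i.mother_id, ind_j.id))  # type: ignore[arg-type]
        self._kin_cache[key] = v
        return v


# -- PED I/O ----------------------------------------------------------------

def read_ped(path: str | Path) -> list[Pedigree]:
    """Read a whitespace-delimited 6-column PED file (PLINK dialect).

    Columns: FID IID PAT MAT SEX PHENO with ``0`` meaning missing parent and
    phenotype coded 1=unaffected, 2=affected, 0/-9=unknown.  Returns one
    :class:`Pedigree` per distinct FID, member order preserved.
    """
    groups: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise PedParseError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(cols)}")
            fid, iid, pat, mat, sex, pheno = cols
            ind = Individual(
                id=iid,
                father_id=None if pat == "0" else pat,
                mother_id=None if mat == "0" else mat,
                sex=Sex.from_ped_code(sex),
                phenotype=Phenotype.from_ped_code(pheno),
            )
            groups.setdefault(fid, []).append(ind)
    if not groups:
        raise PedParseError(f"{path}: no pedigree records")
    return [Pedigree(fid, members) for fid, members in groups.items()]


def write_ped(pedigrees: Iterable[Pedigree], path: str | Path) -> Path:
    """Write pedigrees as 6-column PED (tab-delimited)."""
    path = Path(path)
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped:
                fh.write("\t".join([
                    ped.family_id, m.id,
                    m.father_id or "0", m.mother_id or "0",
                    m.sex.to_ped_code(), m.phenotype.to_ped_code(),
                ]) + "\n")
    return path
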