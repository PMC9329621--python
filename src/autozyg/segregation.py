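"""Recessive co-segregation checking across pedigree members.

A candidate recessive variant must be homozygous-alt in every affected
member, non-homozygous-alt in every unaffected member, and heterozygous in
every genotyped parent of an affected (obligate carrier).  Members with
missing genotypes — and members of unknown phenotype — impose no
constraint.  Cross-family replication keeps a variant only when it
co-segregates in every family that carries it, optionally requiring
homozygous affecteds in at least two families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .pedigree import Pedigree, Phenotype


class SegregationError(ValueError):
    pass


class GenotypeClass(Enum):
    HOM_ALT = "hom"
    HET = "het"
    HOM_REF = "wt"
    MISSING = "missing"


_CODE_TO_CLASS = {2: GenotypeClass.HOM_ALT, 1: GenotypeClass.HET,
                  0: GenotypeClass.HOM_REF, -1: GenotypeClass.MISSING}


def genotype_class(code: int) -> GenotypeClass:
    """Map an alt-allele-count code {2, 1, 0, -1} to Hom/Het/WT/Missing."""
    try:
        return _CODE_TO_CLASS[int(code)]
    except (KeyError, TypeError):
        raise SegregationError(f"invalid genotype code {code!r}") from None


@dataclass
class SegregationVerdict:
    variant_key: str
    consistent: bool
    violations: list[tuple[str, str]] = field(default_factory=list)


def check_recessive_segregation(variant_key: str, pedigree: Pedigree,
                                genotypes: Mapping[str, int]
                                ) -> SegregationVerdict:
    """Test one variant against the fully penetrant recessive model.

    ``genotypes`` maps individual id -> code for the genotyped members;
    absent or -1 entries are skipped.  Raises if no affected member is
    genotyped (the variant is untestable).
    """
    def cls(iid: str) -> GenotypeClass:
        if iid not in genotypes:
            return GenotypeClass.MISSING
        return genotype_class(genotypes[iid])

    if not any(cls(m.id) is not GenotypeClass.MISSING
               for m in pedigree.affected):
        raise SegregationError(
            f"{variant_key}: no genotyped affected member in family "
            f"{pedigree.family_id}")

    violations: list[tuple[str, str]] = []
    for m in pedigree:
        c = cls(m.id)
        if c is GenotypeClass.MISSING:
            continue
        if m.phenotype is Phenotype.AFFECTED and c is not GenotypeClass.HOM_ALT:
            violations.append((m.id, "affected not homozygous-alt"))
        elif m.phenotype is Phenotype.UNAFFECTED and c is GenotypeClass.HOM_ALT:
            violations.append((m.id, "unaffected homozygous-alt"))
    parent_ids = set()
    for m in pedigree.affected:
        parents = pedigree.parents_of(m.id)
        if parents:
            parent_ids.update(parents)
    for pid in sorted(parent_ids):
        c = cls(pid)
        if c is not GenotypeClass.MISSING and c is not GenotypeClass.HET:
            violations.append((pid, "obligate carrier parent not heterozygous"))
    return SegregationVerdict(variant_key, not violations, violations)


def cross_family_replication(
        families: Mapping[str, tuple[Pedigree, Mapping[str, Mapping[str, int]]]],
        *, require_replication: bool = False
) -> dict[str, list[str]]:
    """Screen variants across families; return surviving variant keys.

    ``families`` maps family id -> (pedigree, {variant_key -> {sample:
    code}}).  A family *carries* a variant when any member holds an alt
    allele.  A variant survives iff it is consistent in every carrying
    family and its affecteds are homozygous in at least one family (two
    when ``require_replication``).  Returns {variant_key: [family ids where
    affecteds are homozygous]} for the survivors.
    """
    keys: list[str] = []
    for _, per_variant in families.values():
        for key in per_variant:
            if key not in keys:
                keys.append(key)

    survivors: dict[str, list[str]] = {}
    for key in keys:
        consistent_everywhere = True
        hom_families: list[str] = []
        for fid, (ped, per_variant) in families.items():
            genos = per_variant.get(key)
            if genos is None:
                continue
            carries = any(int(c) in (1, 2) for c in genos.values())
            verdict = check_recessive_segregation(key, ped, genos)
            affected_hom = all(
                genotype_class(genos[m.id]) is GenotypeClass.HOM_ALT
                for m in ped.affected if m.id in genos and genos[m.id] != -1
            ) and any(m.id in genos and genos[m.id] == 2 for m in ped.affected)
            if affected_hom:
                hom_families.append(fid)
            if carries and not verdict.consistent:
                consistent_everywhere = False
                break
        needed = 2 if require_replication else 1
        if consistent_everywhere and len(hom_families) >= needed:
            survivors[key] = hom_families
    return survivors
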