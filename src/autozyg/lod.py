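"""Exact LOD scoring of the fully penetrant recessive hypothesis.

For a sibship whose parents are obligate carriers (het x het mating), the
chance-segregation probability that a child is homozygous for the variant
is 1/4 and that it is not is 3/4.  Under the disease hypothesis —
recessive, 100% penetrant, zero recombination distance — the probability
of observing every affected sibling homozygous and every unaffected
sibling non-homozygous is exactly 1.  The per-family LOD is therefore

    LOD = log10( 1 / ((1/4)^a * (3/4)^u) ) = a*log10(4) + u*log10(4/3)

with ``a`` affected homozygotes and ``u`` unaffected non-homozygotes; any
penetrance-inconsistent observation (affected non-homozygote or unaffected
homozygote) gives likelihood 0 under the hypothesis and a -inf LOD.
Family LODs add.  With a = u = 2 per family the LOD is ~1.45, and two such
families combine to ~2.9 — also the maximum attainable for that design.

``enumerate_lod_oracle`` recomputes the same score by brute force over all
4^n parental transmission patterns, as an independent verification path.

Unaffected siblings always contribute the class-level probability
P(non-homozygous) = 3/4 — not P(het) = 1/2 — even when the observed
genotype distinguishes het from wild type; this is the class-level
observation model the score is defined on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from .pedigree import Pedigree, Phenotype
from .segregation import GenotypeClass, genotype_class

LOG10_4 = math.log10(4.0)
LOG10_4_3 = math.log10(4.0 / 3.0)
NEG_INF = float("-inf")


class LodError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyObservation:
    """Genotype-class tallies of one sibship under carrier x carrier parents.

    ``a``: affected siblings observed homozygous-alt; ``u``: unaffected
    siblings observed non-homozygous; ``inconsistent``: any affected
    non-homozygote or unaffected homozygote was observed.
    """

    family_id: str
    a: int
    u: int
    inconsistent: bool = False

    def __post_init__(self) -> None:
        if self.a < 0 or self.u < 0:
            raise LodError("sibling counts must be non-negative")

    @property
    def null_likelihood(self) -> float:
        """Chance-segregation probability (1/4)^a * (3/4)^u of the observation."""
        return 0.25 ** self.a * 0.75 ** self.u


@dataclass
class LodResult:
    per_family: dict[str, float]
    combined: float
    null_likelihoods: dict[str, float] = field(default_factory=dict)


def observation_from_classes(family_id: str,
                             classes: Sequence[GenotypeClass],
                             affected: Sequence[bool]) -> FamilyObservation:
    """Tally one sibship's observed genotype classes into a FamilyObservation.

    MISSING genotypes are skipped; unknown phenotypes should not be passed.
    """
    if len(classes) != len(affected):
        raise LodError("classes and affected flags differ in length")
    a = u = 0
    inconsistent = False
    for cls, aff in zip(classes, affected):
        if cls is GenotypeClass.MISSING:
            continue
        if aff:
            if cls is GenotypeClass.HOM_ALT:
                a += 1
            else:
                inconsistent = True
        else:
            if cls is GenotypeClass.HOM_ALT:
                inconsistent = True
            else:
                u += 1
    return FamilyObservation(family_id, a, u, inconsistent)


def observe_family(pedigree: Pedigree, genotypes: Mapping[str, int]
                   ) -> FamilyObservation:
    """Build a FamilyObservation from a pedigree and genotype codes.

    The observation covers the sibship of the affected individuals: every
    member with known phenotype sharing both parents with an affected.
    The parents are conditioned as obligate carriers — a genotyped parent
    of an affected that is not heterozygous marks the family inconsistent.
    """
    sib_parent_pairs = {pedigree.parents_of(m.id) for m in pedigree.affected
                        if not m.is_founder}
    sib_parent_pairs.discard(None)
    classes: list[GenotypeClass] = []
    affected: list[bool] = []
    for m in pedigree:
        if m.is_founder or m.phenotype is Phenotype.UNKNOWN:
            continue
        if pedigree.parents_of(m.id) not in sib_parent_pairs:
            continue
        code = genotypes.get(m.id, -1)
        classes.append(genotype_class(code))
        affected.append(m.phenotype is Phenotype.AFFECTED)
    obs = observation_from_classes(pedigree.family_id, classes, affected)
    parent_ids = set()
    for m in pedigree.affected:
        parents = pedigree.parents_of(m.id)
        if parents:
            parent_ids.update(parents)
    for pid in parent_ids:
        cls = genotype_class(genotypes.get(pid, -1))
        if cls not in (GenotypeClass.MISSING, GenotypeClass.HET):
            return FamilyObservation(obs.family_id, obs.a, obs.u, True)
    return obs


def family_lod(obs: FamilyObservation) -> float:
    """LOD of one family, or -inf if inconsistent.

    Computed as log10(1 / ((1/4)^a (3/4)^u)) — numerically identical to the
    enumeration oracle because the null probability 3^u / 4^(a+u) is exactly
    representable in binary floating point — and equal to
    a*log10(4) + u*log10(4/3) up to rounding.
    """
    if obs.inconsistent:
        return NEG_INF
    return -math.log10(obs.null_likelihood)


def combined_lod(observations: Iterable[FamilyObservation]) -> LodResult:
    """Sum family LODs (-inf absorbing) and record per-family null likelihoods."""
    observations = list(observations)
    if not observations:
        raise LodError("need at least one family observation")
    per_family = {o.family_id: family_lod(o) for o in observations}
    nulls = {o.family_id: o.null_likelihood for o in observations}
    return LodResult(per_family, sum(per_family.values()), nulls)


def max_lod(a: int, u: int, families: int = 1) -> float:
    """Maximum combined LOD for ``families`` sibships of a affected + u unaffected.

    Attained by the fully consistent configuration (every affected
    homozygous, every unaffected not); the supremum over all genotype-class
    assignments.
    """
    if a < 0 or u < 0 or families < 0:
        raise LodError("counts must be non-negative")
    return families * (a * LOG10_4 + u * LOG10_4_3)


def enumerate_lod_oracle(classes: Sequence[GenotypeClass],
                         affected: Sequence[bool]) -> float:
    """Brute-force LOD via enumeration of all 4^n parental transmissions.

    Independent verification path for :func:`family_lod`: parents are het x
    het, so each of the n siblings receives one of four equally likely
    allele combinations.  The null probability of the class-level
    observation (affected homozygous; unaffected non-homozygous) is the
    fraction of transmission patterns matching it; the disease-hypothesis
    likelihood is 1 when the observed classes are penetrance-consistent and
    0 otherwise.
    """
    if len(classes) != len(affected):
        raise LodError("classes and affected flags differ in length")
    if len(classes) > 8:
        raise LodError("oracle enumeration limited to 8 siblings")

    observed = [(c, aff) for c, aff in zip(classes, affected)
                if c is not GenotypeClass.MISSING]
    for cls, aff in observed:
        if aff and cls is not GenotypeClass.HOM_ALT:
            return NEG_INF
        if not aff and cls is GenotypeClass.HOM_ALT:
            return NEG_INF
    n = len(observed)
    if n == 0:
        return 0.0
    matches = 0
    for pattern in product((0, 1), repeat=2 * n):
        ok = True
        for k, (cls, aff) in enumerate(observed):
            n_alt = pattern[2 * k] + pattern[2 * k + 1]
            hom = n_alt == 2
            if aff != hom:
                ok = False
                break
        matches += ok
    p_null = matches / 4 ** n
    return -math.log10(p_null)
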