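"""Pairwise relatedness from SNP genotypes: IBS counts and method-of-moments IBD.

For each sample pair the SNPs with both calls present are classified by
identity by state (IBS 0/1/2).  The genome-wide method of moments converts
the observed IBS counts into estimated probabilities Z0/Z1/Z2 of sharing
0/1/2 alleles identical by descent, using the expected IBS-class counts
implied by the allele frequencies:

    E[IBS0 | IBD 0] = sum 2 p^2 q^2
    E[IBS1 | IBD 0] = sum 4 p^3 q + 4 p q^3
    E[IBS1 | IBD 1] = sum 2 p^2 q + 2 p q^2
    E[IBS2 | IBD 2] = n

Z0 = N_IBS0 / E[IBS0|0]; Z1 = (N_IBS1 - Z0 E[IBS1|0]) / E[IBS1|1];
Z2 = 1 - Z0 - Z1; the triple is then projected onto the probability
simplex (negatives clamped, renormalised).  The genome-shared fraction is
PI_HAT = Z1/2 + Z2 (0.5 for parent-offspring and full siblings, ~1/32 for
second cousins, 0 for unrelateds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .simulate import GenotypeMatrix


class RelatednessError(ValueError):
    pass


@dataclass
class IbsCounts:
    i: str
    j: str
    n0: int
    n1: int
    n2: int
    n_used: int
    used: np.ndarray | None = None  # variant indices behind the counts

    def __post_init__(self) -> None:
        if self.n0 + self.n1 + self.n2 != self.n_used:
            raise RelatednessError("IBS counts must sum to n_used")


@dataclass
class IbdEstimate:
    i: str
    j: str
    z0: float
    z1: float
    z2: float
    pi_hat: float
    counts: IbsCounts | None = None


def _polymorphic_mask(g: GenotypeMatrix) -> np.ndarray:
    """SNPs whose observed alt-allele frequency lies strictly in (0, 1).

    Frequency-based on purpose: excluding sites because all *genotypes*
    happen to coincide would condition on the pair's own sharing and bias
    the IBD estimate downward.
    """
    freqs = g.alt_frequencies()
    return ~np.isnan(freqs) & (freqs > 0.0) & (freqs < 1.0)


def ibs_counts(g: GenotypeMatrix, i: str, j: str,
               mask: np.ndarray | None = None) -> IbsCounts:
    """Count IBS 0/1/2 SNPs for one sample pair.

    SNPs monomorphic across the matrix's samples, or missing in either
    member of the pair, are excluded.  IBS2 = equal codes; IBS0 = opposite
    homozygotes; IBS1 otherwise.
    """
    if i == j:
        raise RelatednessError("IBS counts require two distinct samples")
    ci = g.genotypes_of(i).astype(np.int16)
    cj = g.genotypes_of(j).astype(np.int16)
    if mask is None:
        mask = _polymorphic_mask(g)
    ok = mask & (ci >= 0) & (cj >= 0)
    used = np.flatnonzero(ok)
    a, b = ci[used], cj[used]
    ibs2 = int(np.sum(a == b))
    ibs0 = int(np.sum(np.abs(a - b) == 2))
    n = used.size
    return IbsCounts(i, j, ibs0, n - ibs0 - ibs2, ibs2, n, used)


def mom_ibd(counts: IbsCounts, freqs: Sequence[float]) -> IbdEstimate:
    """Method-of-moments IBD estimate from IBS counts and allele frequencies.

    ``freqs`` is the full per-variant alt-frequency array the counts were
    taken from (the SNPs actually used are selected via ``counts.used``),
    or an array of exactly ``n_used`` frequencies.
    """
    freqs = np.asarray(freqs, dtype=float)
    if counts.used is not None and freqs.size != counts.used.size:
        freqs = freqs[counts.used]
    if freqs.size != counts.n_used:
        raise RelatednessError(
            f"need {counts.n_used} frequencies, got {freqs.size}")
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise RelatednessError("allele frequencies must lie in (0, 1)")
    p, q = freqs, 1.0 - freqs
    e0_ibs0 = float(np.sum(2.0 * p ** 2 * q ** 2))
    e0_ibs1 = float(np.sum(4.0 * p ** 3 * q + 4.0 * p * q ** 3))
    e1_ibs1 = float(np.sum(2.0 * p ** 2 * q + 2.0 * p * q ** 2))
    if e0_ibs0 <= 0.0 or e1_ibs1 <= 0.0:
        raise RelatednessError("degenerate allele frequencies: zero expected IBS")
    z0 = counts.n0 / e0_ibs0
    z1 = (counts.n1 - z0 * e0_ibs1) / e1_ibs1
    z2 = 1.0 - z0 - z1
    z = np.clip([z0, z1, z2], 0.0, None)
    total = z.sum()
    z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
    pi_hat = z[1] / 2.0 + z[2]
    return IbdEstimate(counts.i, counts.j, *map(float, z), float(pi_hat), counts)


def pair_ibd(g: GenotypeMatrix, i: str, j: str,
             freqs: Sequence[float]) -> IbdEstimate:
    """IBD estimate for one pair given known per-variant allele frequencies.

    Sites with degenerate frequencies (<= 0 or >= 1, or NaN) are excluded;
    no genotype-based site exclusion is applied.
    """
    freqs = np.asarray(freqs, dtype=float)
    mask = ~np.isnan(freqs) & (freqs > 0.0) & (freqs < 1.0)
    counts = ibs_counts(g, i, j, mask=mask)
    return mom_ibd(counts, freqs)


RELATEDNESS_COLUMNS = ["I", "J", "N_USED", "IBS0", "IBS1", "IBS2",
                       "Z0", "Z1", "Z2", "PI_HAT"]


def pairwise_matrix(g: GenotypeMatrix,
                    samples: Sequence[str] | None = None,
                    pedigree: Pedigree | Sequence[Pedigree] | None = None,
                    freqs: Sequence[float] | None = None) -> pd.DataFrame:
    """IBD estimates for all unordered sample pairs.

    Allele frequencies come from, in order of precedence: the ``freqs``
    argument; the founders of the supplied pedigree(s); all samples (a
    biased fallback for small cohorts).  Monomorphic SNPs and SNPs with
    degenerate frequency estimates are excluded.
    """
    samples = list(samples) if samples is not None else list(g.samples)
    if len(samples) < 2:
        raise RelatednessError("need at least two samples")
    if freqs is None:
        if pedigree is not None:
            peds = [pedigree] if isinstance(pedigree, Pedigree) else list(pedigree)
            founder_ids = [m.id for p in peds for m in p.founders
                           if m.id in g.samples]
            freqs = g.alt_frequencies(founder_ids)
        else:
            freqs = g.alt_frequencies()
    freqs = np.asarray(freqs, dtype=float)
    mask = ~np.isnan(freqs) & (freqs > 0.0) & (freqs < 1.0)

    rows = []
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            c = ibs_counts(g, samples[a], samples[b], mask=mask)
            est = mom_ibd(c, freqs)
            rows.append((est.i, est.j, c.n_used, c.n0, c.n1, c.n2,
                         est.z0, est.z1, est.z2, est.pi_hat))
    return pd.DataFrame(rows, columns=RELATEDNESS_COLUMNS)
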