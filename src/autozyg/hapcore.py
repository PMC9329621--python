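"""Conserved homozygous core around an index variant.

Carriers of a founder mutation from different families share, besides the
variant itself, a surrounding interval on which all of them are homozygous
for identical alleles — the remnant of the ancestral haplotype.  Starting
from an index variant at which every sample is homozygous, the core
expands SNP by SNP left and right while all samples remain homozygous and
(by default) mutually allele-identical, stopping at the first violating
SNP.  The interval length (last - first SNP position + 1) and the SNP
count are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix


class HapcoreError(ValueError):
    pass


@dataclass(frozen=True)
class CoreInterval:
    chrom: str
    start: int   # bp of first SNP in the core
    end: int     # bp of last SNP in the core
    n_snps: int
    index_key: str

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def _chrom_context(g: GenotypeMatrix, chrom: str, pos: int
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    g.variant_index(chrom, pos)  # raises if absent
    mask = (g.variants["CHROM"].astype(str) == str(chrom)).to_numpy()
    idx = np.flatnonzero(mask)
    positions = g.variants["POS"].to_numpy()[idx]
    if np.any(np.diff(positions) <= 0):
        raise HapcoreError(f"variants on {chrom} are not sorted by position")
    j = int(np.searchsorted(positions, pos))
    return idx, positions, j


def core_interval(g: GenotypeMatrix, index: tuple[str, int],
                  samples: Sequence[str],
                  *, require_same_allele: bool = True,
                  missing_breaks: bool = True) -> CoreInterval:
    """Expand the shared homozygous core around ``index = (chrom, pos)``.

    Every sample must be homozygous at the index SNP.  At each successive
    SNP outward, all samples must be homozygous and — unless
    ``require_same_allele`` is disabled — carry the same allele as each
    other; the first violating SNP is excluded.  Missing genotypes stop
    the expansion by default (``missing_breaks``) or are skipped (not
    counted, not breaking) otherwise.  The result is anti-monotone in the
    sample set: adding samples can only shrink the core.
    """
    samples = list(samples)
    if not samples:
        raise HapcoreError("need at least one sample")
    chrom, pos = index
    idx, positions, j = _chrom_context(g, str(chrom), int(pos))
    sub = g.codes[[g.sample_index(s) for s in samples]][:, idx]

    def status(k: int) -> str:
        col = sub[:, k]
        if np.any(col == -1):
            return "missing"
        if np.any(col == 1):
            return "break"
        if require_same_allele and np.unique(col).size > 1:
            return "break"
        return "ok"

    if status(j) != "ok":
        raise HapcoreError(
            f"samples not all homozygous{' for one allele' if require_same_allele else ''} "
            f"at index {chrom}:{pos}")

    included = [j]
    for step in (-1, +1):
        k = j + step
        while 0 <= k < len(idx):
            st = status(k)
            if st == "break" or (st == "missing" and missing_breaks):
                break
            if st == "ok":
                included.append(k)
            k += step  # missing + skip policy: continue past the SNP
    included.sort()
    key = g.variant_key(int(idx[j]))
    return CoreInterval(str(chrom), int(positions[included[0]]),
                        int(positions[included[-1]]), len(included), key)


def window_genotypes(g: GenotypeMatrix, index: tuple[str, int],
                     radius_bp: int, samples: Sequence[str]) -> pd.DataFrame:
    """Genotype sub-table of all SNPs within +-radius of the index position.

    Rows are SNPs in positional order (columns CHROM, POS plus one column
    per sample).
    """
    if radius_bp <= 0:
        raise HapcoreError("radius must be positive")
    samples = list(samples)
    if not samples:
        raise HapcoreError("need at least one sample")
    chrom, pos = index
    idx, positions, _ = _chrom_context(g, str(chrom), int(pos))
    keep = np.abs(positions - int(pos)) <= radius_bp
    out = pd.DataFrame({
        "CHROM": str(chrom),
        "POS": positions[keep],
    })
    for s in samples:
        out[s] = g.codes[g.sample_index(s)][idx[keep]]
    return out.reset_index(drop=True)
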