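"""Gene-dropping pedigree simulator with recombination.

Produces the synthetic stand-in for family whole-genome data: founders
receive two uniquely labelled haplotypes with alleles drawn independently
per site from a given frequency; each meiosis draws a Poisson number of
crossovers (mean = chromosome genetic length in Morgans) placed uniformly
along the chromosome (no interference, no obligate chiasma); children
inherit recombined parental haplotypes.  Because every allele carries a
founder-haplotype label, autozygosity — both alleles descending from one
founder haplotype — is known exactly: the ground-truth tracts a runs-of-
homozygosity caller should recover.

The module also plants a fully penetrant recessive causal variant inside an
autozygous tract of the affected siblings (rejection sampling), draws
annotation columns (MAF, CADD, functional class) for the variant table, and
writes/reads the standard file formats (VCF/PED/TSV/BED) so the whole
discovery funnel is exercisable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

_BASES = "ACGT"


class SimulationError(ValueError):
    """Invalid simulation input or exhausted rejection sampling."""


# -- genetic map ------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    morgans: float


@dataclass
class GeneticMap:
    """Chromosome sizes plus sorted variant positions (1-based bp)."""

    chromosomes: list[Chromosome]
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            if chrom.morgans <= 0 and chrom.morgans != 0.0:
                raise SimulationError(f"{chrom.name}: genetic length must be >= 0")
            pos = np.asarray(self.positions.get(chrom.name, ()), dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise SimulationError(
                    f"{chrom.name}: variant positions must be strictly increasing")
            if pos.size and (pos[0] < 1 or pos[-1] > chrom.length_bp):
                raise SimulationError(f"{chrom.name}: positions outside chromosome")
            self.positions[chrom.name] = pos

    @property
    def n_variants(self) -> int:
        return int(sum(self.positions[c.name].size for c in self.chromosomes))

    def variant_table(self) -> pd.DataFrame:
        """One row per variant (CHROM, POS, REF, ALT), chromosomes in map order."""
        rows = []
        i = 0
        for chrom in self.chromosomes:
            for pos in self.positions[chrom.name]:
                rows.append((chrom.name, int(pos), _BASES[i % 4], _BASES[(i + 1) % 4]))
                i += 1
        return pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT"])

    @staticmethod
    def uniform(n_chromosomes: int = 2,
                length_bp: int = 100_000_000,
                cm_per_mb: float = 1.0,
                variants_per_chromosome: int = 10_000) -> "GeneticMap":
        """Evenly spaced variants on equally sized chromosomes named "1", "2", ..."""
        morgans = length_bp / 1e6 * cm_per_mb / 100.0
        chroms = [Chromosome(str(k + 1), length_bp, morgans)
                  for k in range(n_chromosomes)]
        spacing = length_bp // (variants_per_chromosome + 1)
        pos = (np.arange(1, variants_per_chromosome + 1) * spacing).astype(np.int64)
        return GeneticMap(chroms, {c.name: pos.copy() for c in chroms})


# -- containers -------------------------------------------------------------

@dataclass(frozen=True)
class AutozygosityTract:
    """Maximal interval where a sample's two founder-haplotype labels coincide."""

    sample: str
    chrom: str
    start: int  # bp, inclusive
    end: int    # bp, exclusive

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise SimulationError("tract end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenotypeMatrix:
    """Samples x variants genotypes, alt-allele-count coded (-1 = missing).

    ``origins``, when present (simulated data), holds the founder-haplotype
    label of both alleles per sample x variant; equal labels mean the site
    is autozygous in that sample.
    """

    samples: list[str]
    variants: pd.DataFrame  # columns CHROM POS REF ALT
    codes: np.ndarray       # (n_samples, n_variants) int8
    origins: np.ndarray | None = None  # (n_samples, n_variants, 2) int32

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.variants)):
            raise SimulationError("codes shape does not match samples x variants")
        if not np.isin(self.codes, (-1, 0, 1, 2)).all():
            raise SimulationError("genotype codes must be in {-1, 0, 1, 2}")
        self._sample_index = {s: k for k, s in enumerate(self.samples)}
        self._variant_index = {
            (c, int(p)): k
            for k, (c, p) in enumerate(zip(self.variants["CHROM"], self.variants["POS"]))
        }

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise SimulationError(f"unknown sample {sample!r}") from None

    def variant_index(self, chrom: str, pos: int) -> int:
        try:
            return self._variant_index[(str(chrom), int(pos))]
        except KeyError:
            raise SimulationError(f"no variant at {chrom}:{pos}") from None

    def variant_key(self, idx: int) -> str:
        row = self.variants.iloc[idx]
        return f"{row.CHROM}:{row.POS}:{row.REF}:{row.ALT}"

    def genotypes_of(self, sample: str) -> np.ndarray:
        return self.codes[self.sample_index(sample)]

    def genotype(self, sample: str, chrom: str, pos: int) -> int:
        return int(self.codes[self.sample_index(sample),
                              self.variant_index(chrom, pos)])

    def alt_frequencies(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Observed alt-allele frequency per variant (NaN where all missing)."""
        idx = [self.sample_index(s) for s in samples] if samples is not None \
            else slice(None)
        sub = self.codes[idx].astype(float)
        sub[sub < 0] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(sub, axis=0) / 2.0


# -- haplotype drop ---------------------------------------------------------

# A haplotype along one chromosome: piecewise-constant founder labels.
# breaks[k] is the (bp, float) start of segment k; labels[k] its label.
_Hap = tuple[np.ndarray, np.ndarray]


def _recombine(h0: _Hap, h1: _Hap, xs: np.ndarray, first: int, length: float) -> _Hap:
    if xs.size == 0:
        src = h0 if first == 0 else h1
        return src[0].copy(), src[1].copy()
    bounds = np.concatenate([[0.0], xs, [length]])
    out_breaks: list[float] = []
    out_labels: list[int] = []
    for k in range(len(bounds) - 1):
        a, b = bounds[k], bounds[k + 1]
        if a >= b:
            continue
        br, lb = h0 if (first + k) % 2 == 0 else h1
        i0 = int(np.searchsorted(br, a, "right")) - 1
        i1 = int(np.searchsorted(br, b, "left"))
        for t in range(i0, i1):
            s = max(float(br[t]), a)
            if out_labels and out_labels[-1] == lb[t]:
                continue  # merge contiguous equal-label segments
            out_breaks.append(s)
            out_labels.append(int(lb[t]))
    return np.asarray(out_breaks), np.asarray(out_labels)


def _meiosis(haps: tuple[_Hap, _Hap], chrom: Chromosome,
             rng: np.random.Generator) -> _Hap:
    n_x = int(rng.poisson(chrom.morgans))
    xs = np.sort(rng.uniform(0.0, chrom.length_bp, size=n_x))
    first = int(rng.integers(2))
    return _recombine(haps[0], haps[1], xs, first, chrom.length_bp)


def _drop_haplotypes(p: Pedigree, gmap: GeneticMap, rng: np.random.Generator
                     ) -> tuple[dict[str, dict[str, tuple[_Hap, _Hap]]], list[str]]:
    """Drop founder haplotypes through the pedigree.

    Returns per-individual, per-chromosome haplotype pairs (paternal,
    maternal) and the founder-haplotype label table: label ``2k``/``2k+1``
    belongs to the k-th founder in pedigree order.
    """
    founders = [m.id for m in p.founders]
    founder_label = {fid: 2 * k for k, fid in enumerate(founders)}
    haps: dict[str, dict[str, tuple[_Hap, _Hap]]] = {}
    for ind in p.topological_order():
        per_chrom: dict[str, tuple[_Hap, _Hap]] = {}
        for chrom in gmap.chromosomes:
            if ind.is_founder:
                lab = founder_label[ind.id]
                per_chrom[chrom.name] = (
                    (np.array([0.0]), np.array([lab])),
                    (np.array([0.0]), np.array([lab + 1])),
                )
            else:
                pat = _meiosis(haps[ind.father_id][chrom.name], chrom, rng)
                mat = _meiosis(haps[ind.mother_id][chrom.name], chrom, rng)
                per_chrom[chrom.name] = (pat, mat)
        haps[ind.id] = per_chrom
    return haps, founders


def _labels_at(hap: _Hap, positions: np.ndarray) -> np.ndarray:
    br, lb = hap
    return lb[np.searchsorted(br, positions.astype(float), "right") - 1]


def _autozygous_intervals(pair: tuple[_Hap, _Hap], length: int
                          ) -> list[tuple[int, int]]:
    (brA, lbA), (brB, lbB) = pair
    pts = np.union1d(brA, brB)
    ends = np.append(pts[1:], float(length))
    out: list[tuple[int, int]] = []
    for s, e in zip(pts, ends):
        if e <= s:
            continue
        la = lbA[np.searchsorted(brA, s, "right") - 1]
        lb_ = lbB[np.searchsorted(brB, s, "right") - 1]
        if la == lb_:
            si, ei = int(round(s)), int(round(e))
            if out and out[-1][1] == si:
                out[-1] = (out[-1][0], ei)
            elif ei > si:
                out.append((si, ei))
    return out


def _tracts_from_haps(haps, gmap: GeneticMap, sample_ids: Sequence[str]
                      ) -> list[AutozygosityTract]:
    tracts = []
    for sid in sample_ids:
        for chrom in gmap.chromosomes:
            for s, e in _autozygous_intervals(haps[sid][chrom.name], chrom.length_bp):
                tracts.append(AutozygosityTract(sid, chrom.name, s, e))
    return tracts


def simulate_tracts(p: Pedigree, gmap: GeneticMap, seed: int,
                    samples: Sequence[str] | None = None
                    ) -> list[AutozygosityTract]:
    """Haplotype-drop only: ground-truth autozygosity tracts, no genotypes.

    Cheap enough for Monte Carlo studies of autozygous genome fractions
    (e.g. verifying the 1/16 expectation for first-cousin offspring).
    """
    rng = np.random.default_rng(seed)
    haps, _ = _drop_haplotypes(p, gmap, rng)
    ids = list(samples) if samples is not None else [m.id for m in p]
    return _tracts_from_haps(haps, gmap, ids)


def autozygous_fraction(tracts: Iterable[AutozygosityTract], sample: str,
                        gmap: GeneticMap) -> float:
    """Fraction of the mapped genome autozygous in ``sample``."""
    total = sum(c.length_bp for c in gmap.chromosomes)
    shared = sum(t.length for t in tracts if t.sample == sample)
    return shared / total


# -- genotype simulation ----------------------------------------------------

def _check_freqs(freqs: np.ndarray, gmap: GeneticMap) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size != gmap.n_variants:
        raise SimulationError(
            f"need {gmap.n_variants} founder frequencies, got {freqs.size}")
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise SimulationError("founder allele frequencies must lie in (0, 1)")
    return freqs


def _assemble(p: Pedigree, gmap: GeneticMap, haps, founder_alleles: np.ndarray,
              rng: np.random.Generator, genotype_error_rate: float,
              protect: int | None = None
              ) -> tuple[GenotypeMatrix, list[AutozygosityTract]]:
    sample_ids = [m.id for m in p]
    n, m = len(sample_ids), gmap.n_variants
    codes = np.empty((n, m), dtype=np.int8)
    origins = np.empty((n, m, 2), dtype=np.int32)
    col = 0
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom.name]
        sl = slice(col, col + pos.size)
        vidx = np.arange(col, col + pos.size)
        for si, sid in enumerate(sample_ids):
            hA, hB = haps[sid][chrom.name]
            la = _labels_at(hA, pos)
            lb = _labels_at(hB, pos)
            codes[si, sl] = founder_alleles[la, vidx] + founder_alleles[lb, vidx]
            origins[si, sl, 0] = la
            origins[si, sl, 1] = lb
        col += pos.size
    if genotype_error_rate > 0.0:
        hom = codes != 1
        flip = hom & (rng.random(codes.shape) < genotype_error_rate)
        if protect is not None:
            flip[:, protect] = False
        codes[flip] = 1
    g = GenotypeMatrix(sample_ids, gmap.variant_table(), codes, origins)
    return g, _tracts_from_haps(haps, gmap, sample_ids)


def simulate_genotypes(p: Pedigree, gmap: GeneticMap,
                       founder_freqs: Sequence[float], seed: int,
                       *, genotype_error_rate: float = 0.0
                       ) -> tuple[GenotypeMatrix, list[AutozygosityTract]]:
    """Gene-drop genotypes for every pedigree member.

    Founder haplotype alleles are Bernoulli(frequency) per site; children
    inherit recombined haplotypes (Poisson crossovers, uniform positions).
    ``genotype_error_rate`` flips homozygous calls to heterozygous with the
    given per-genotype probability (observational error; the haplotype
    ground truth, and hence the returned tracts, are unaffected).
    Deterministic given ``seed``.
    """
    freqs = _check_freqs(np.asarray(founder_freqs), gmap)
    rng = np.random.default_rng(seed)
    haps, founders = _drop_haplotypes(p, gmap, rng)
    founder_alleles = (rng.random((2 * len(founders), freqs.size)) < freqs
                       ).astype(np.int8)
    return _assemble(p, gmap, haps, founder_alleles, rng, genotype_error_rate)


def plant_causal_variant(p: Pedigree, gmap: GeneticMap,
                         founder_freqs: Sequence[float],
                         affected_ids: Sequence[str],
                         causal: tuple[str, int],
                         *, max_retries: int = 100_000, seed: int = 0,
                         genotype_error_rate: float = 0.0
                         ) -> tuple[GenotypeMatrix, list[AutozygosityTract]]:
    """Rejection-sample replicates until the causal site segregates recessively.

    Accepts a replicate when, at ``causal = (chrom, pos)``, every designated
    affected individual is homozygous alt *and* autozygous, and every
    unaffected pedigree member is non-homozygous-alt — i.e. the phenotype is
    consistent with a fully penetrant recessive variant.  Each attempt draws
    only the haplotype structure and the causal-site founder alleles; the
    remaining sites (independent of the acceptance event) are filled in
    after acceptance.  The planted site is exempt from genotype error.
    """
    freqs = _check_freqs(np.asarray(founder_freqs), gmap)
    chrom_name, pos = causal
    table = gmap.variant_table()
    match = np.flatnonzero((table["CHROM"] == str(chrom_name)).to_numpy()
                           & (table["POS"] == int(pos)).to_numpy())
    if match.size == 0:
        raise SimulationError(f"causal position {chrom_name}:{pos} not on the map")
    ci = int(match[0])

    if not affected_ids:
        return simulate_genotypes(p, gmap, freqs, seed,
                                  genotype_error_rate=genotype_error_rate)
    for sid in affected_ids:
        p.member(sid)

    unaffected = [m.id for m in p.unaffected]
    pos_arr = np.array([pos], dtype=np.int64)
    q = freqs[ci]
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        haps, founders = _drop_haplotypes(p, gmap, rng)
        causal_col = (rng.random(2 * len(founders)) < q).astype(np.int8)

        def _code(sid: str) -> tuple[int, bool]:
            hA, hB = haps[sid][chrom_name]
            la = int(_labels_at(hA, pos_arr)[0])
            lb = int(_labels_at(hB, pos_arr)[0])
            return int(causal_col[la] + causal_col[lb]), la == lb

        ok = all(code == 2 and auto for code, auto in map(_code, affected_ids)) \
            and all(_code(sid)[0] != 2 for sid in unaffected)
        if ok:
            founder_alleles = (rng.random((2 * len(founders), freqs.size)) < freqs
                               ).astype(np.int8)
            founder_alleles[:, ci] = causal_col
            return _assemble(p, gmap, haps, founder_alleles, rng,
                             genotype_error_rate, protect=ci)
    raise SimulationError(
        f"planting failed: 0 acceptances in {max_retries} attempts "
        f"(causal {chrom_name}:{pos}, founder alt frequency {q:g})")


# -- annotations ------------------------------------------------------------

#: Annotation values forced onto the planted causal variant: essentially
#: absent from population databases, deleterious CADD, protein-coding.
CAUSAL_MAF = 1e-5
CAUSAL_CADD = 21.4
CAUSAL_CLASS = "exonic"

ANNOTATION_COLUMNS = ["CHROM", "POS", "REF", "ALT", "GENE", "MAF", "CADD", "CLASS"]


def simulate_annotations(g: GenotypeMatrix, causal: tuple[str, int] | None,
                         seed: int) -> pd.DataFrame:
    """Draw database-style annotations (MAF, CADD, class) per variant.

    Background variants: MAF from a 0.9/0.1 mixture of Uniform(0.01, 0.5)
    (common) and Uniform(0, 0.001) (rare); CADD ~ Uniform(0, 40); class
    categorical with P(exonic)=0.01, P(splice)=0.002, P(other)=0.988.  The
    causal variant, when given, is forced to MAF=1e-5, CADD=21.4, exonic.
    """
    rng = np.random.default_rng(seed)
    m = g.n_variants
    rare = rng.random(m) < 0.1
    maf = np.where(rare, rng.uniform(0.0, 0.001, m), rng.uniform(0.01, 0.5, m))
    cadd = rng.uniform(0.0, 40.0, m)
    cls = rng.choice(np.array(["exonic", "splice", "other"]), size=m,
                     p=[0.01, 0.002, 0.988])
    df = g.variants.copy()
    df["GENE"] = [f"GENE_{c}_{int(p) // 1_000_000:03d}"
                  for c, p in zip(df["CHROM"], df["POS"])]
    df["MAF"] = maf
    df["CADD"] = cadd
    df["CLASS"] = cls
    if causal is not None:
        ci = g.variant_index(*causal)
        df.loc[df.index[ci], ["MAF", "CADD", "CLASS"]] = \
            [CAUSAL_MAF, CAUSAL_CADD, CAUSAL_CLASS]
    return df[ANNOTATION_COLUMNS]
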