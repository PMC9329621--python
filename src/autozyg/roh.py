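"""Runs-of-homozygosity detection and shared-region intersection.

The caller reimplements the classic SNP-window RoH scan used in
homozygosity mapping: a fixed-size window of consecutive SNPs slides one
SNP at a time; a window is "homozygous" when it contains at most a small
number of heterozygous and missing calls; each SNP is scored by the
proportion of overlapping windows that are homozygous; maximal stretches of
passing SNPs, split at large physical gaps, become segments after minimum
SNP-count, length and density filters.  Defaults follow the documented
defaults of the standard tool: 50-SNP window, <=1 heterozygote and <=5
missing per window, hit proportion 0.05, >=100 SNPs, >=1000 kb, >=1 SNP
per 50 kb, gaps split above 1000 kb.

Shared regions across affected individuals are the interval intersection
of the per-sample segment unions — the autozygosity-mapping signal that
localises a recessive disease variant in consanguineous families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .simulate import GenotypeMatrix


class RoHError(ValueError):
    pass


@dataclass(frozen=True)
class RoHParams:
    """Window-scan thresholds (all positive; hit proportion in (0, 1])."""

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    hit_proportion: float = 0.05
    min_snps: int = 100
    min_length_kb: float = 1000.0
    min_density_snps_per_kb: float = 1.0 / 50.0
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.window_snps, self.min_snps) <= 0 or \
                min(self.min_length_kb, self.min_density_snps_per_kb,
                    self.max_gap_kb) <= 0:
            raise RoHError("RoH parameters must be positive")
        if not 0.0 < self.hit_proportion <= 1.0:
            raise RoHError("hit proportion must lie in (0, 1]")


@dataclass(frozen=True)
class RoHSegment:
    sample: str
    chrom: str
    start: int  # bp of first SNP in the run
    end: int    # bp of last SNP in the run
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _in_run_snps(het: np.ndarray, miss: np.ndarray, params: RoHParams
                 ) -> np.ndarray:
    """Boolean per-SNP in-run flags from the sliding-window scan."""
    n = het.size
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(miss)])
    het_w = het_c[w:] - het_c[:-w]           # window j covers SNPs [j, j+w)
    mis_w = mis_c[w:] - mis_c[:-w]
    ok = (het_w <= params.max_het_per_window) & \
         (mis_w <= params.max_missing_per_window)
    ok_c = np.concatenate([[0], np.cumsum(ok)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n - w)
    n_hom = ok_c[hi + 1] - ok_c[lo]
    n_cov = hi - lo + 1
    return n_hom / n_cov >= params.hit_proportion - 1e-12


def call_roh(g: GenotypeMatrix, sample: str,
             params: RoHParams = RoHParams()) -> list[RoHSegment]:
    """Call runs of homozygosity for one sample.

    Variants must be sorted by (chrom, pos); missing genotypes are never
    counted as heterozygous.  Returned segments are non-overlapping, span
    first-to-last SNP bp, and satisfy every threshold in ``params``.
    """
    codes = g.genotypes_of(sample)
    segments: list[RoHSegment] = []
    for chrom in dict.fromkeys(g.variants["CHROM"]):
        mask = (g.variants["CHROM"] == chrom).to_numpy()
        pos = g.variants.loc[mask, "POS"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise RoHError(f"variants on {chrom} are not sorted by position")
        c = codes[mask]
        in_run = _in_run_snps(c == 1, c == -1, params)
        run_idx = np.flatnonzero(in_run)
        if run_idx.size == 0:
            continue
        # split at index discontinuities and physical gaps > max_gap
        gap_bp = np.diff(pos[run_idx])
        breaks = np.flatnonzero((np.diff(run_idx) > 1) |
                                (gap_bp > params.max_gap_kb * 1000.0))
        for chunk in np.split(run_idx, breaks + 1):
            n_snps = chunk.size
            start, end = int(pos[chunk[0]]), int(pos[chunk[-1]])
            length_kb = (end - start) / 1000.0
            if n_snps < params.min_snps or length_kb < params.min_length_kb:
                continue
            if length_kb > 0 and n_snps / length_kb < params.min_density_snps_per_kb:
                continue
            segments.append(RoHSegment(sample, str(chrom), start, end, n_snps))
    return segments


# -- interval algebra -------------------------------------------------------

Interval = tuple[str, int, int]  # (chrom, start, end); end exclusive


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of possibly overlapping intervals, sorted, per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        merged: list[list[int]] = []
        for s, e in sorted(by_chrom[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend((chrom, s, e) for s, e in merged)
    return out


def _intersect_two(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    by_chrom_b: dict[str, list[Interval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv[0], []).append(iv)
    for chrom, s1, e1 in a:
        for _, s2, e2 in by_chrom_b.get(chrom, ()):
            s, e = max(s1, s2), min(e1, e2)
            if e > s:
                out.append((chrom, s, e))
    return merge_intervals(out)


def intersect_interval_sets(sets: Sequence[Sequence[Interval]]) -> list[Interval]:
    result = merge_intervals(sets[0])
    for nxt in sets[1:]:
        result = _intersect_two(result, merge_intervals(nxt))
    return result


def shared_roh(segments_by_sample: Mapping[str, Sequence[RoHSegment]],
               samples: Iterable[str],
               min_length_bp: int = 0) -> list[Interval]:
    """Maximal intervals covered by a segment of *every* listed sample.

    Intersections shorter than ``min_length_bp`` are dropped.  Adding a
    sample can only shrink the result.
    """
    samples = list(samples)
    if not samples:
        raise RoHError("shared_roh needs at least one sample")
    sets = []
    for sid in samples:
        if sid not in segments_by_sample:
            raise RoHError(f"no RoH segments supplied for sample {sid!r}")
        sets.append([(seg.chrom, seg.start, seg.end)
                     for seg in segments_by_sample[sid]])
    shared = intersect_interval_sets(sets)
    return [iv for iv in shared if iv[2] - iv[1] >= min_length_bp]


def total_length_mb(intervals: Iterable[Interval]) -> float:
    """Total span in Mb after merging overlaps."""
    return sum(e - s for _, s, e in merge_intervals(intervals)) / 1e6


def jaccard(a: Iterable[Interval], b: Iterable[Interval]) -> float:
    """Base-pair Jaccard index between two interval sets (1.0 if both empty)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    inter = sum(e - s for _, s, e in _intersect_two(ma, mb))
    union = sum(e - s for _, s, e in merge_intervals(list(ma) + list(mb)))
    return inter / union if union else 1.0
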