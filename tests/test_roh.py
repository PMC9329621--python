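"""RoH caller vs direct window enumeration, shared-region algebra, and
recovery of planted autozygosity tracts."""

import numpy as np
import pytest

import autozyg as az
from autozyg.roh import RoHError, RoHParams, intersect_interval_sets, \
    merge_intervals
from conftest import single_sample_matrix


def enumerate_in_run_snps(codes, params: RoHParams):
    """Brute-force reference for the sliding-window in-run definition."""
    n = len(codes)
    w = params.window_snps
    windows = []
    for j in range(n - w + 1):
        chunk = codes[j:j + w]
        het = sum(1 for c in chunk if c == 1)
        mis = sum(1 for c in chunk if c == -1)
        windows.append(het <= params.max_het_per_window
                       and mis <= params.max_missing_per_window)
    in_run = []
    for i in range(n):
        covering = [windows[j] for j in range(max(0, i - w + 1),
                                              min(i, n - w) + 1)]
        if covering and sum(covering) / len(covering) >= params.hit_proportion:
            in_run.append(i)
    return in_run


def hom_run_fixture(het_in_middle: bool = False):
    """500 homozygous SNPs spanning 3 Mb flanked by dense heterozygous SNPs."""
    flank = 200
    left_pos = [1000 * (k + 1) for k in range(flank)]
    run_start = left_pos[-1] + 1000
    run_pos = [run_start + 6000 * k for k in range(500)]
    right_pos = [run_pos[-1] + 1000 * (k + 1) for k in range(flank)]
    codes = [1] * flank + [0, 2] * 250 + [1] * flank
    if het_in_middle:
        codes[flank + 250] = 1
    return single_sample_matrix(codes, positions=left_pos + run_pos + right_pos)


class TestCallRoh:
    def test_single_run_matches_enumeration_oracle(self):
        g = hom_run_fixture()
        params = RoHParams()
        segs = az.call_roh(g, "S1", params)
        oracle = enumerate_in_run_snps(list(g.codes[0]), params)
        assert len(segs) == 1
        seg = segs[0]
        pos = g.variants.POS.to_numpy()
        # hit-proportion scoring sheds at most the outermost run SNP per side
        interior = set(pos[202:698])
        covered = set(p for p in pos if seg.start <= p <= seg.end)
        assert interior <= covered
        assert covered <= set(pos[198:702])  # no spill into the het flanks
        # segment bounds equal the oracle's in-run stretch exactly
        assert seg.start == pos[oracle[0]] and seg.end == pos[oracle[-1]]
        assert seg.n_snps == len(oracle)

    def test_all_heterozygous_is_empty(self):
        g = single_sample_matrix([1] * 600)
        assert az.call_roh(g, "S1") == []

    def test_single_embedded_het_does_not_split(self):
        params = RoHParams(max_het_per_window=1)
        segs = az.call_roh(hom_run_fixture(het_in_middle=True), "S1", params)
        assert len(segs) == 1
        oracle = enumerate_in_run_snps(
            list(hom_run_fixture(het_in_middle=True).codes[0]), params)
        assert np.all(np.diff(oracle) == 1)  # contiguous despite the het

    def test_output_respects_thresholds(self):
        g = hom_run_fixture()
        params = RoHParams()
        for seg in az.call_roh(g, "S1", params):
            assert seg.n_snps >= params.min_snps
            assert seg.length >= params.min_length_kb * 1000
            assert seg.n_snps / (seg.length / 1000) >= \
                params.min_density_snps_per_kb

    def test_unsorted_variants_rejected(self):
        g = single_sample_matrix([0, 0, 0], positions=[100, 50, 200])
        with pytest.raises(RoHError, match="sorted"):
            az.call_roh(g, "S1")

    def test_unknown_sample(self):
        with pytest.raises(Exception, match="unknown sample"):
            az.call_roh(single_sample_matrix([0, 0]), "nobody")

    def test_recovers_planted_tracts(self, default_run):
        """Calls cover >=95% of long tracts; <5% of called bases are false."""
        report, fixture, _ = default_run
        g = fixture.genotypes
        affected = [m.id for ped in fixture.pedigrees for m in ped.affected]
        covered_num = covered_den = false_bp = called_bp = 0
        for sid in affected:
            called = [(s.chrom, s.start, s.end)
                      for s in az.call_roh(g, sid)]
            truth = [(t.chrom, t.start, t.end) for t in fixture.tracts
                     if t.sample == sid]
            long_truth = [iv for iv in truth if iv[2] - iv[1] >= 2_000_000]
            inter = intersect_interval_sets([called, long_truth]) \
                if called and long_truth else []
            covered_num += sum(e - s for _, s, e in inter)
            covered_den += sum(e - s for _, s, e in merge_intervals(long_truth))
            called_total = sum(e - s for _, s, e in merge_intervals(called))
            in_truth = intersect_interval_sets([called, truth]) \
                if called and truth else []
            false_bp += called_total - sum(e - s for _, s, e in in_truth)
            called_bp += called_total
        assert covered_den > 0
        assert covered_num / covered_den >= 0.95
        assert false_bp / called_bp < 0.05


class TestSharedRoh:
    seg = az.RoHSegment

    def test_identical_segments_idempotent(self):
        s = {"a": [self.seg("a", "1", 10, 100, 50)],
             "b": [self.seg("b", "1", 10, 100, 50)]}
        assert az.shared_roh(s, ["a", "b"]) == [("1", 10, 100)]

    def test_partial_overlap(self):
        s = {"a": [self.seg("a", "1", 10_000_000, 20_000_000, 500)],
             "b": [self.seg("b", "1", 15_000_000, 25_000_000, 500)]}
        assert az.shared_roh(s, ["a", "b"]) == [("1", 15_000_000, 20_000_000)]

    def test_adding_sample_never_enlarges(self):
        s = {"a": [self.seg("a", "1", 0, 100, 10)],
             "b": [self.seg("b", "1", 50, 200, 10)],
             "c": [self.seg("c", "1", 80, 90, 5)]}
        two = az.shared_roh(s, ["a", "b"])
        three = az.shared_roh(s, ["a", "b", "c"])
        assert sum(e - x for _, x, e in three) <= sum(e - x for _, x, e in two)

    def test_empty_sample_set_rejected(self):
        with pytest.raises(RoHError, match="at least one"):
            az.shared_roh({}, [])

    def test_shared_covers_planted_intersection(self, default_run):
        """Shared RoH of the affected sibs recovers their common tract."""
        report, fixture, _ = default_run
        ped = fixture.pedigrees[0]
        affected = [m.id for m in ped.affected]
        segs = {sid: az.call_roh(fixture.genotypes, sid) for sid in affected}
        shared = az.shared_roh(segs, affected)
        truth = intersect_interval_sets([
            [(t.chrom, t.start, t.end) for t in fixture.tracts
             if t.sample == sid] for sid in affected])
        truth = [iv for iv in truth if iv[2] - iv[1] >= 2_000_000]
        assert az.jaccard(shared, truth) >= 0.9


class TestTotalLength:
    def test_empty(self):
        assert az.total_length_mb([]) == 0.0

    def test_disjoint(self):
        assert az.total_length_mb([("1", 0, 1_000_000),
                                   ("1", 2_000_000, 3_000_000)]) == 2.0

    def test_overlapping_merged_first(self):
        assert az.total_length_mb([("1", 0, 2_000_000),
                                   ("1", 1_000_000, 3_000_000)]) == 3.0
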