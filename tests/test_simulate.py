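"""Gene-dropping simulator: Mendelian consistency, autozygosity ground
truth, causal-variant planting, annotations, and fixture round-trips."""

import numpy as np
import pandas as pd
import pytest

import autozyg as az
from autozyg.pedigree import Individual, Pedigree
from autozyg.simulate import SimulationError


@pytest.fixture(scope="module")
def small_map() -> az.GeneticMap:
    return az.GeneticMap.uniform(n_chromosomes=1, length_bp=50_000_000,
                                 variants_per_chromosome=1000)


@pytest.fixture(scope="module")
def trio() -> Pedigree:
    return Pedigree("T", [Individual("dad"), Individual("mum"),
                          Individual("kid", "dad", "mum")])


def mendelian_ok(f: np.ndarray, m: np.ndarray, c: np.ndarray) -> bool:
    """Child alt count bounded by what the parents can transmit."""
    lo = (f == 2).astype(int) + (m == 2).astype(int)
    hi = 2 - (f == 0).astype(int) - (m == 0).astype(int)
    return bool(np.all((c >= lo) & (c <= hi)))


class TestSimulateGenotypes:
    def test_trio_mendelian_consistent(self, trio, small_map):
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0.1, 0.9, small_map.n_variants)
        g, _ = az.simulate_genotypes(trio, small_map, freqs, seed=5)
        assert mendelian_ok(g.genotypes_of("dad"), g.genotypes_of("mum"),
                            g.genotypes_of("kid"))

    def test_whole_pedigree_mendelian_consistent(self, cousin_family,
                                                 small_map):
        ped, _ = cousin_family
        freqs = np.random.default_rng(1).uniform(0.1, 0.9,
                                                 small_map.n_variants)
        g, _ = az.simulate_genotypes(ped, small_map, freqs, seed=9)
        for m in ped:
            parents = ped.parents_of(m.id)
            if parents:
                assert mendelian_ok(g.genotypes_of(parents[0]),
                                    g.genotypes_of(parents[1]),
                                    g.genotypes_of(m.id))

    def test_deterministic_given_seed(self, trio, small_map):
        freqs = np.full(small_map.n_variants, 0.3)
        g1, t1 = az.simulate_genotypes(trio, small_map, freqs, seed=7)
        g2, t2 = az.simulate_genotypes(trio, small_map, freqs, seed=7)
        assert np.array_equal(g1.codes, g2.codes)
        assert t1 == t2

    def test_autozygous_sites_are_homozygous(self, cousin_family, small_map):
        ped, _ = cousin_family
        freqs = np.full(small_map.n_variants, 0.5)
        g, _ = az.simulate_genotypes(ped, small_map, freqs, seed=11)
        auto = g.origins[..., 0] == g.origins[..., 1]
        assert np.all(g.codes[auto] != 1)

    def test_first_cousin_offspring_inbreeding(self, cousin_family):
        """Mean autozygous genome fraction approaches F = 1/16."""
        ped, _ = cousin_family
        gmap = az.GeneticMap.uniform(n_chromosomes=1,
                                     variants_per_chromosome=10)
        fracs = []
        for rep in range(400):
            tracts = az.simulate_tracts(ped, gmap, seed=rep,
                                        samples=["F1_D1"])
            fracs.append(az.autozygous_fraction(tracts, "F1_D1", gmap))
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 1 / 16) <= 3 * se

    def test_zero_recombination_all_or_none(self, cousin_family):
        ped, _ = cousin_family
        chrom = az.simulate.Chromosome("1", 10_000_000, 0.0)
        gmap = az.GeneticMap([chrom], {"1": np.array([5_000_000])})
        for rep in range(30):
            tracts = az.simulate_tracts(ped, gmap, seed=rep,
                                        samples=["F1_D1"])
            for t in tracts:
                assert (t.start, t.end) == (0, 10_000_000)

    def test_sibling_ibd_fraction_averages_half(self, trio, small_map):
        """Realized parent-child... full-sib pairwise IBD averages 0.5."""
        ped = Pedigree("S", [Individual("dad"), Individual("mum"),
                             Individual("k1", "dad", "mum"),
                             Individual("k2", "dad", "mum")])
        gmap = az.GeneticMap.uniform(n_chromosomes=2,
                                     variants_per_chromosome=10)
        shares = []
        for rep in range(200):
            g, _ = az.simulate_genotypes(
                ped, gmap, np.full(gmap.n_variants, 0.5), seed=rep)
            o1 = g.origins[g.sample_index("k1")]
            o2 = g.origins[g.sample_index("k2")]
            ibd = ((o1[:, 0] == o2[:, 0]).astype(int)
                   + (o1[:, 1] == o2[:, 1]).astype(int))
            shares.append(ibd.mean() / 2)
        shares = np.asarray(shares)
        se = shares.std(ddof=1) / np.sqrt(len(shares))
        assert abs(shares.mean() - 0.5) <= 3 * se

    def test_bad_frequencies_rejected(self, trio, small_map):
        with pytest.raises(SimulationError, match="\\(0, 1\\)"):
            az.simulate_genotypes(trio, small_map,
                                  np.full(small_map.n_variants, 1.0), seed=0)
        with pytest.raises(SimulationError, match="frequencies"):
            az.simulate_genotypes(trio, small_map, [0.5, 0.5], seed=0)

    def test_genotype_error_introduces_heterozygotes(self, cousin_family,
                                                     small_map):
        ped, _ = cousin_family
        freqs = np.full(small_map.n_variants, 0.5)
        g0, _ = az.simulate_genotypes(ped, small_map, freqs, seed=3)
        g1, _ = az.simulate_genotypes(ped, small_map, freqs, seed=3,
                                      genotype_error_rate=0.05)
        flipped = (g0.codes != 1) & (g1.codes == 1)
        assert flipped.sum() > 0
        assert np.all(g1.codes[g0.codes == 1] == 1)


class TestPlantCausalVariant:
    def test_affected_hom_parents_het(self, cousin_family):
        ped, affected = cousin_family
        gmap = az.GeneticMap.uniform(n_chromosomes=1,
                                     variants_per_chromosome=200)
        freqs = np.full(gmap.n_variants, 0.5)
        causal = ("1", int(gmap.positions["1"][100]))
        g, tracts = az.plant_causal_variant(ped, gmap, freqs, affected,
                                            causal, seed=2)
        for sid in affected:
            assert g.genotype(sid, *causal) == 2
            idx = g.variant_index(*causal)
            o = g.origins[g.sample_index(sid), idx]
            assert o[0] == o[1]  # autozygous
        for parent in ("F1_C1", "F1_C2"):
            assert g.genotype(parent, *causal) == 1
        for m in ped.unaffected:
            assert g.genotype(m.id, *causal) != 2

    def test_empty_affected_set_is_plain_simulation(self, cousin_family):
        ped, _ = cousin_family
        gmap = az.GeneticMap.uniform(n_chromosomes=1,
                                     variants_per_chromosome=50)
        freqs = np.full(gmap.n_variants, 0.4)
        causal = ("1", int(gmap.positions["1"][10]))
        g1, _ = az.plant_causal_variant(ped, gmap, freqs, [], causal, seed=4)
        g2, _ = az.simulate_genotypes(ped, gmap, freqs, seed=4)
        assert np.array_equal(g1.codes, g2.codes)

    def test_impossible_constraint_exhausts_retries(self, cousin_family):
        ped, affected = cousin_family
        gmap = az.GeneticMap.uniform(n_chromosomes=1,
                                     variants_per_chromosome=50)
        freqs = np.full(gmap.n_variants, 1e-12)
        causal = ("1", int(gmap.positions["1"][10]))
        with pytest.raises(SimulationError, match="attempts"):
            az.plant_causal_variant(ped, gmap, freqs, affected, causal,
                                    seed=0, max_retries=30)

    def test_off_map_position_rejected(self, cousin_family):
        ped, affected = cousin_family
        gmap = az.GeneticMap.uniform(n_chromosomes=1,
                                     variants_per_chromosome=50)
        with pytest.raises(SimulationError, match="not on the map"):
            az.plant_causal_variant(ped, gmap,
                                    np.full(gmap.n_variants, 0.5),
                                    affected, ("1", 12345), seed=0)


class TestSimulateAnnotations:
    def make_matrix(self, n: int) -> az.GenotypeMatrix:
        gmap = az.GeneticMap.uniform(n_chromosomes=1,
                                     variants_per_chromosome=n)
        return az.GenotypeMatrix(["X"], gmap.variant_table(),
                                 np.zeros((1, n), dtype=np.int8))

    def test_causal_row_forced(self):
        g = self.make_matrix(100)
        causal = ("1", int(g.variants.POS.iloc[50]))
        ann = az.simulate_annotations(g, causal, seed=0)
        row = ann[(ann.CHROM == "1") & (ann.POS == causal[1])].iloc[0]
        assert (row.MAF, row.CADD, row.CLASS) == (1e-5, 21.4, "exonic")

    def test_deterministic(self):
        g = self.make_matrix(500)
        a1 = az.simulate_annotations(g, None, seed=33)
        a2 = az.simulate_annotations(g, None, seed=33)
        pd.testing.assert_frame_equal(a1, a2)

    def test_rare_fraction_matches_mixture(self):
        g = self.make_matrix(100_000)
        ann = az.simulate_annotations(g, None, seed=1)
        frac = (ann.MAF <= 0.001).mean()
        se = np.sqrt(0.1 * 0.9 / len(ann))
        assert abs(frac - 0.1) <= 3 * se

    def test_absent_causal_position(self):
        g = self.make_matrix(10)
        with pytest.raises(SimulationError, match="no variant"):
            az.simulate_annotations(g, ("1", 999_999_999), seed=0)


@pytest.fixture(scope="module")
def bundle(tmp_path_factory, cousin_family):
    ped, affected = cousin_family
    gmap = az.GeneticMap.uniform(n_chromosomes=2,
                                 variants_per_chromosome=100)
    freqs = np.random.default_rng(0).uniform(0.2, 0.8, gmap.n_variants)
    g, tracts = az.simulate_genotypes(ped, gmap, freqs, seed=1)
    g.codes[0, 5] = -1  # exercise missing-genotype coding
    ann = az.simulate_annotations(g, None, seed=2)
    out = tmp_path_factory.mktemp("fixture")
    paths = az.write_fixture(g, [ped], ann, out, tracts=tracts)
    return g, ped, ann, tracts, paths


class TestFixtureRoundTrip:
    def test_vcf_round_trip(self, bundle):
        g, _, _, _, paths = bundle
        back = az.read_vcf(paths["vcf"])
        assert back.samples == g.samples
        assert np.array_equal(back.codes, g.codes)
        pd.testing.assert_frame_equal(back.variants, g.variants)

    def test_vcf_gt_coding(self, bundle):
        g, _, _, _, paths = bundle
        body = [l for l in paths["vcf"].read_text().splitlines()
                if not l.startswith("#")]
        gts = body[5].split("\t")[9:]
        assert gts[0] == "./."  # code -1
        coding = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for k, sample_gt in enumerate(gts):
            assert sample_gt == coding[int(g.codes[k, 5])]

    def test_tract_bed_round_trip_and_convention(self, bundle):
        _, _, _, tracts, paths = bundle
        back = az.read_tracts_bed(paths["tracts"])
        assert set(back) == set(tracts)
        first = paths["tracts"].read_text().splitlines()[0].split("\t")
        assert int(first[2]) > int(first[1]) >= 0  # 0-based half-open

    def test_annotation_round_trip(self, bundle):
        _, _, ann, _, paths = bundle
        back = az.read_annotations(paths["annotations"])
        pd.testing.assert_frame_equal(back, ann)
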