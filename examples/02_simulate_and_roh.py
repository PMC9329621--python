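"""Gene-drop a consanguineous family and map runs of homozygosity.

Simulates a 12-member family whose parents are first cousins, plants a
recessive causal variant inside an autozygous tract of the two affected
siblings, calls RoH per affected sibling, and intersects them: the shared
homozygous regions that localise the causal variant.
"""

import numpy as np

import autozyg as az

ped, affected = az.first_cousin_sibship("F1", prefix="F1_")
gmap = az.GeneticMap.uniform(n_chromosomes=2, length_bp=100_000_000,
                             variants_per_chromosome=10_000)
freqs = np.random.default_rng(7).uniform(0.05, 0.95, gmap.n_variants)
causal = ("1", int(gmap.positions["1"][5000]))
freqs[5000] = 0.5

g, tracts = az.plant_causal_variant(ped, gmap, freqs, affected, causal,
                                    seed=11)
print(f"causal site {causal[0]}:{causal[1]} genotypes:",
      {s: g.genotype(s, *causal) for s in ("F1_C1", "F1_C2", "F1_D1",
                                           "F1_D2", "F1_D3")})

segments = {sid: az.call_roh(g, sid) for sid in affected}
for sid, segs in segments.items():
    mb = sum(s.length for s in segs) / 1e6
    truth = sum(t.length for t in tracts if t.sample == sid) / 1e6
    print(f"{sid}: {len(segs)} RoH segments, {mb:.1f} Mb called "
          f"(ground-truth autozygosity {truth:.1f} Mb)")

shared = az.shared_roh(segments, affected)
print(f"shared by both affected siblings: {len(shared)} regions, "
      f"{az.total_length_mb(shared):.1f} Mb")
hit = any(c == causal[0] and s <= causal[1] < e for c, s, e in shared)
print(f"causal variant inside a shared region: {hit}")
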