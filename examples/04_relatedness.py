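"""IBS counts and method-of-moments IBD across relationship classes.

Simulates the first-cousin family and estimates pairwise genome sharing
(PI_HAT = Z1/2 + Z2) for an unrelated founder pair, the first-cousin
parents, and a full-sib pair, using the true founder allele frequencies.
"""

import numpy as np

import autozyg as az

ped, _ = az.first_cousin_sibship("F1", prefix="F1_")
gmap = az.GeneticMap.uniform(n_chromosomes=6, length_bp=100_000_000,
                             cm_per_mb=1.5, variants_per_chromosome=3400)
freqs = np.random.default_rng(5).uniform(0.1, 0.9, gmap.n_variants)
g, _ = az.simulate_genotypes(ped, gmap, freqs, seed=21)

pairs = {
    "unrelated founders": ("F1_A1", "F1_B2"),
    "first cousins": ("F1_C1", "F1_C2"),
    "full siblings": ("F1_D3", "F1_D4"),
    "parent-child": ("F1_C1", "F1_D3"),
}
print(f"{'pair':22s} {'pedigree 2*phi':>14s} {'PI_HAT':>8s}   Z0/Z1/Z2")
for label, (i, j) in pairs.items():
    est = az.pair_ibd(g, i, j, freqs)
    exp = ped.expected_ibd(i, j)  # slightly above 0.5 for the inbred sibs
    print(f"{label:22s} {exp:14.4f} {est.pi_hat:8.4f}   "
          f"{est.z0:.2f}/{est.z1:.2f}/{est.z2:.2f}")
# Estimates track the realized sharing of one simulated genome, which
# scatters around the pedigree expectation for a finite genetic map.
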