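"""Conserved homozygous core around a shared candidate variant.

When affected individuals from two families carry the same recessive
variant inherited from a distant common ancestor, they share only a short
ancestral haplotype around it.  This script builds the default two-family
cohort and measures that conserved core.
"""

import tempfile

import autozyg as az

with tempfile.TemporaryDirectory() as tmp:
    report, fixture = az.run_default_fixture(seed=5, out_dir=tmp)

g = fixture.genotypes
affected = [m.id for ped in fixture.pedigrees for m in ped.affected]

within = az.core_interval(g, fixture.causal, affected[:2])
print(f"core within one family:  {within.length_bp / 1e3:.1f} kb, "
      f"{within.n_snps} SNPs")
across = az.core_interval(g, fixture.causal, affected)
print(f"core across both families: {across.length_bp / 1e3:.1f} kb, "
      f"{across.n_snps} SNPs")
# Adding carriers from the second family shrinks the conserved interval:
# recombination in the two lineages trimmed the ancestral haplotype
# independently, so only a short core flanking the variant survives.

win = az.window_genotypes(g, fixture.causal, radius_bp=70_000,
                          samples=affected)
print(f"SNPs within a 140 kb window around the variant: {len(win)}")
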