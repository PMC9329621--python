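# Methods

This note records the models, algorithms, numerical choices and known
limitations behind `autozyg`. It documents what the code computes; every
number quoted here is produced by the test suite, the examples, or
`scripts/acceptance.py`.

## Pedigree model and expected IBD

Pedigrees are directed family graphs; consanguineous loops (parents who
share an ancestor) are allowed, and only ancestor *cycles* are rejected.
Kinship uses the classic recursion — founders mutually unrelated,
φ(i,i) = ½(1 + φ(father, mother)), φ(i,j) = ½(φ(father_i, j) +
φ(mother_i, j)) for i not an ancestor of j — with the recursion always
descending on the later-generation member, which keeps the boundary
condition valid in looped pedigrees. The expected genome fraction shared
IBD between distinct members is reported as 2φ. This outbred
approximation slightly overstates sharing for inbred pairs (it ignores
condensed identity states); it is exact for outbred pairs, e.g. 0.5 for
parent–offspring and 1/32 for second cousins. Kinship is verified in the
tests against an independent single-locus gene-dropping Monte Carlo
(2·10⁵ drops, 3-standard-error agreement).

PED files use the 6-column PLINK dialect (FID IID PAT MAT SEX PHENO;
phenotype 1/2/0/−9, parent "0" = missing). Sex is read but unused by the
analysis.

## Gene-dropping simulator

Founders receive two uniquely labelled haplotypes whose alleles are drawn
independently per site from supplied frequencies in (0, 1). Each meiosis
draws a crossover count ~ Poisson(chromosome genetic length in Morgans)
with positions uniform on the chromosome: no interference and no obligate
chiasma — the simplest process with the correct expected map length.
Haplotypes are piecewise-constant label functions over base pairs, so
autozygosity tracts (intervals where a sample's two labels coincide) are
exact, not discretised to SNP positions. There is no mutation model, so
autozygous sites are homozygous exactly; an optional per-genotype error
rate (default 0) flips homozygous calls to heterozygous to stress the RoH
caller's heterozygote allowance.

The causal-variant planter rejection-samples replicates until, at the
chosen site, every designated affected sibling is homozygous-alt *and*
autozygous while every unaffected member is non-homozygous-alt; obligate-
carrier parents come out heterozygous automatically. Each attempt draws
only the haplotype structure and the causal-site founder alleles; the
remaining sites are filled after acceptance. Because non-causal alleles
are independent of the acceptance event, this is distributionally
identical to naive rejection over full replicates and roughly an order of
magnitude faster. With the default first-cousin loop and a causal-site
founder frequency of 0.5, acceptance is of order 10⁻²–10⁻³ per attempt.

**Default fixture.** Two families, each a 12-member first-cousin loop
(two great-grandparents, two of their children plus two married-in
founders, the two first-cousin parents, and four siblings of whom the
first two are affected); independent founder sets; two 100 Mb chromosomes
at 1 cM/Mb with 10,000 evenly spaced variants each; background founder
frequencies Uniform(0.05, 0.95); one causal site (frequency 0.5, placed
mid-chromosome) planted per family. These sizes give multi-Mb autozygous
tracts and a minutes-scale full test run on one CPU. A first-cousin loop
cannot be expressed with fewer than 12 members, which is why the family
size exceeds the six genotyped members a typical study reports.

**Annotations.** Database-style columns are synthetic: background MAF
from a 0.9/0.1 mixture of Uniform(0.01, 0.5) and Uniform(0, 0.001), CADD
~ Uniform(0, 40), class categorical (exonic 0.01, splice 0.002, other
0.988); the causal variant is forced to MAF 10⁻⁵, CADD 21.4, exonic.
These are fixture choices that make the funnel's selectivity realistic
(roughly 10% of variants rare, ~1% coding), not estimates of any real
annotation resource. The simulator draws founder alleles independently
per site, so the fixture has no linkage disequilibrium among founder
haplotypes; consequences are noted under Limitations.

## Runs of homozygosity

The caller reimplements the standard SNP-window scan: a window of 50
consecutive SNPs slides one SNP at a time; a window qualifies when it has
≤1 heterozygous and ≤5 missing calls; a SNP is in-run when ≥5% of the
windows covering it qualify; maximal in-run stretches are split at
physical gaps >1000 kb and filtered to ≥100 SNPs, ≥1000 kb, and ≥1 SNP
per 50 kb. Missing genotypes never count as heterozygous. Coordinates
span first-to-last SNP. The hit-proportion rule sheds at most the
outermost run SNP on each side of a true segment (the tests pin this
behaviour against a direct window-enumeration oracle); at tract scales of
tens of Mb the boundary cost is negligible, and on the default fixture
the caller covers ≥95% of ground-truth tracts longer than 2 Mb with <5%
of called bases outside any tract. Thresholds are the cited window
method's documented defaults; the analysis is intended for autosomes.

Shared regions are the interval intersection of the per-sample segment
unions across the listed samples — anti-monotone in the sample set.

## Prioritization funnel

Stage order is fixed: homozygous-alt in all affected samples → MAF →
CADD → functional class, applied to variants already restricted to the
shared homozygous regions. Thresholds are inclusive (MAF ≤ 0.001,
CADD ≥ 15) with a strict-mode flag. Missing MAF counts as rare (absent
from population databases) and missing CADD fails the CADD stage; both
policies are flags. Region membership tests the 1-based variant position
against half-open intervals (kept at the start, dropped at the end);
`regions_from_bed` converts 0-based half-open BED.

## Segregation and replication

The recessive checker requires every affected member homozygous-alt,
every unaffected member non-homozygous-alt, and every *genotyped* parent
of an affected heterozygous; ungenotyped members and unknown phenotypes
impose no constraint. Cross-family replication keeps a variant only if it
is consistent in every family carrying at least one alt allele and its
affecteds are homozygous in ≥1 family (≥2 when replication is required).
Compound heterozygosity and non-recessive models are out of scope.

## Recessive LOD

Under a carrier × carrier mating, P(child homozygous) = 1/4. The family
LOD for a affected homozygotes and u unaffected non-homozygotes is
log10(1/((1/4)^a (3/4)^u)); inconsistent observations score −∞, which is
absorbing under cross-family addition. Unaffected siblings always
contribute the class-level 3/4 — not P(het) = 1/2 — even when the
genotype distinguishes het from wild type: the hypothesis is scored on
the homozygous/non-homozygous partition. Parents conditioned as obligate
carriers contribute factor 1 to both likelihoods. There is no
recombination-fraction grid (θ = 0) and no penetrance parameter (fixed
at 1).

Numerics: the null probability 3^u/4^(a+u) is exactly representable in
binary floating point, so the closed form and the independent 4^n
transmission-enumeration oracle (≤8 siblings) return bit-identical LODs;
the tests assert exact equality on 200 random consistent configurations.
The sibship maximum a·log10 4 + u·log10(4/3) is confirmed by exhaustive
enumeration over all 3^(a+u) genotype-class assignments.

## Relatedness

Per pair, SNPs with both calls present are classified IBS 0/1/2 (equal
codes; opposite homozygotes; otherwise). Site exclusion is
frequency-based — observed or supplied allele frequency strictly inside
(0, 1) — deliberately *not* based on whether the cohort's genotypes
happen to coincide at a site, which would condition on the pair's own
sharing and bias the estimate downward. The method-of-moments estimator
uses the expected IBS-class counts given the allele frequencies
(E[IBS0|IBD0] = Σ2p²q², E[IBS1|IBD0] = Σ4p³q+4pq³, E[IBS1|IBD1] =
Σ2p²q+2pq²), solves Z0, Z1 sequentially, sets Z2 = 1−Z0−Z1, projects onto
the probability simplex, and reports PI_HAT = Z1/2 + Z2.

Allele frequencies come from the supplied array, else from pedigree
founders, else from all samples; the all-sample fallback is biased for
small cohorts. Two further caveats are inherent to this estimator and
documented rather than patched: (i) with few founders behind the
frequency estimates, cross-family PI_HAT acquires an upward bias of order
0.1; (ii) the moments equations assume Hardy–Weinberg (outbred) genotype
proportions, so pairs involving inbred individuals (e.g. the first-cousin
offspring, F = 1/16) are inflated — the tests therefore assert the
near-zero cross-family bound on outbred members, while sib pairs and
unrelated outbred pairs estimate 0.5 and 0 within 0.05 given true
frequencies. No LD pruning is implemented; the fixture founders carry no
LD.

## Haplotype core

Starting from an index variant at which every listed sample is
homozygous, the core expands SNP by SNP while all samples stay homozygous
and (by default) allele-identical; the first violating SNP is excluded.
Missing genotypes break the expansion by default (flag to skip instead).
Allele identity is compared on genotype codes, not phase — matching what
array/WGS genotypes provide. Interval length is last − first included SNP
position + 1 bp, reported alongside the SNP count. A laxer
homozygosity-only rule is available via `require_same_allele=False`.

## Pipeline

`run_pipeline` executes, in fixed order: input validation (every PED
member must appear in the VCF) → per-family shared RoH of the affected →
funnel on the discovery (first) family's shared regions → segregation
with replication → LOD for the survivors → pairwise relatedness
(founder-based frequencies) → haplotype core per final candidate. The
JSON report is schema-versioned, sorted-key, timestamp-free, and
byte-identical across reruns with the same inputs and seed; logs go to
standard error. On the default fixture the planted variant is recovered
as the unique final candidate in ≥90% of 20 seeded replicates (and is
always present), with a combined LOD of 2.908.

## What passing tests do and do not show

The synthetic cohort emulates the *structure* of family-based recessive
discovery: autozygosity tracts of realistic length, a causal variant
inside them, annotation-funnel selectivity, independent replication. It
does not emulate linkage disequilibrium, population founder haplotype
structure, genotyping-array ascertainment, variant-calling error
profiles, or real annotation databases. Passing the recovery tests shows
the algorithms are correct and the pipeline's logic is sound on data of
the assumed structure; it does not certify performance on real WGS
cohorts, where annotation quality and RoH parameter choice dominate.

## Known limitations

- Autosomal, biallelic SNVs only; no X-linked kinship or hemizygosity.
- The 2φ IBD expectation and the moments IBD estimator both assume
  outbred individuals; inbred pairs are approximated (see above).
- No model-based (HMM) RoH calling; the window method's thresholds are
  the reconstructable defaults, and results on real data depend on them.
- Recessive, fully penetrant, homozygous-by-descent hypothesis only — no
  compound heterozygosity, phenocopies, or reduced penetrance.
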