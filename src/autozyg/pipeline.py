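"""End-to-end discovery pipeline: RoH -> funnel -> segregation -> LOD -> ...

Orchestrates the full recessive-variant discovery analysis on VCF + PED +
annotation-TSV inputs: per-family shared runs of homozygosity for the
affected siblings, the variant prioritization funnel on the discovery
family's shared regions, co-segregation checking with cross-family
replication, exact recessive LOD scoring of the surviving candidates,
pairwise relatedness, and the conserved haplotype core around each final
candidate.  All randomness (there is none at analysis time; the seed
matters only for fixture generation) and every stage artifact is recorded
in a machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from . import io as az_io
from .funnel import filter_funnel, restrict_to_regions
from .hapcore import HapcoreError, core_interval
from .lod import combined_lod, observe_family
from .pedigree import Pedigree, Phenotype, read_ped
from .relatedness import pairwise_matrix
from .roh import RoHParams, call_roh, shared_roh, total_length_mb
from .segregation import cross_family_replication
from .simulate import (GeneticMap, GenotypeMatrix, plant_causal_variant,
                       simulate_annotations)

logger = logging.getLogger("autozyg")

SCHEMA_VERSION = 1


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    vcf: Path
    ped: Path
    annotations: Path
    out_dir: Path
    roh_params: RoHParams = field(default_factory=RoHParams)
    maf_max: float = 0.001
    cadd_min: float = 15.0
    classes: tuple[str, ...] = ("exonic", "splice")
    require_replication: bool = True
    inclusive_thresholds: bool = True
    missing_maf_is_rare: bool = True
    min_shared_length_bp: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        roh = RoHParams(**raw.pop("roh_params", {}))
        classes = tuple(raw.pop("classes", ("exonic", "splice")))
        for key in ("vcf", "ped", "annotations", "out_dir"):
            raw[key] = Path(raw[key])
        return cls(roh_params=roh, classes=classes, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in fixed order; return (and write) the JSON report.

    Identical inputs and seed produce a byte-identical ``report.json``.
    Stage errors abort with the stage name; a PED member absent from the
    VCF is a validation error before stage 1.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    g = az_io.read_vcf(config.vcf)
    pedigrees = read_ped(config.ped)
    annotations = az_io.read_annotations(config.annotations)
    missing = [m.id for ped in pedigrees for m in ped if m.id not in g.samples]
    if missing:
        raise PipelineError(
            f"pedigree members absent from VCF: {', '.join(missing)}")

    report: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                    "n_samples": len(g.samples), "n_variants": g.n_variants}

    # Stage 1: per-family shared RoH of the affected siblings.
    shared_by_family: dict[str, list] = {}
    roh_summary = {}
    for ped in pedigrees:
        affected = [m.id for m in ped.affected]
        if not affected:
            raise PipelineError(f"family {ped.family_id}: no affected member")
        segs = {sid: call_roh(g, sid, config.roh_params) for sid in affected}
        for sid, s in segs.items():
            az_io.write_regions_bed([(x.chrom, x.start - 1, x.end) for x in s],
                                    out_dir / f"roh_{sid}.bed")
        shared = shared_roh(segs, affected,
                            min_length_bp=config.min_shared_length_bp)
        shared_by_family[ped.family_id] = shared
        roh_summary[ped.family_id] = {
            "n_regions": len(shared),
            "total_mb": round(total_length_mb(shared), 3),
        }
        az_io.write_regions_bed([(c, s - 1, e) for c, s, e in shared],
                                out_dir / f"shared_roh_{ped.family_id}.bed")
        logger.info("family %s: %d shared RoH regions, %.1f Mb",
                    ped.family_id, len(shared), total_length_mb(shared))
    report["shared_roh"] = roh_summary

    # Stage 2: prioritization funnel on the discovery (first) family.
    discovery = pedigrees[0]
    disc_affected = [m.id for m in discovery.affected]
    regions = [(c, s, e + 1) for c, s, e in shared_by_family[discovery.family_id]]
    restricted = restrict_to_regions(annotations, regions)
    funnel = filter_funnel(restricted, g, disc_affected,
                           maf_max=config.maf_max, cadd_min=config.cadd_min,
                           classes=config.classes,
                           inclusive=config.inclusive_thresholds,
                           missing_maf_is_rare=config.missing_maf_is_rare)
    funnel.survivors.to_csv(out_dir / "funnel_survivors.tsv", sep="\t",
                            index=False)
    report["funnel"] = {"discovery_family": discovery.family_id,
                        "stages": [[name, n] for name, n in funnel.stages]}
    logger.info("funnel stages: %s", funnel.stages)

    # Stage 3: segregation + cross-family replication.
    survivor_keys = [f"{r.CHROM}:{r.POS}:{r.REF}:{r.ALT}"
                     for r in funnel.survivors.itertuples(index=False)]
    families = {}
    for ped in pedigrees:
        per_variant = {}
        for key, row in zip(survivor_keys, funnel.survivors.itertuples(index=False)):
            per_variant[key] = {m.id: g.genotype(m.id, row.CHROM, row.POS)
                                for m in ped}
        families[ped.family_id] = (ped, per_variant)
    survivors = cross_family_replication(
        families, require_replication=config.require_replication)
    candidates = sorted(survivors)
    report["candidates"] = candidates
    report["segregation"] = {k: survivors[k] for k in candidates}

    # Stage 4: recessive LOD for each surviving candidate.
    lod_report = {}
    for key in candidates:
        chrom, pos = key.split(":")[:2]
        observations = [
            observe_family(ped, {m.id: g.genotype(m.id, chrom, int(pos))
                                 for m in ped})
            for ped in pedigrees
        ]
        res = combined_lod(observations)
        lod_report[key] = {
            "per_family": {f: round(v, 4) for f, v in res.per_family.items()},
            "combined": round(res.combined, 4),
            "null_likelihoods": {f: round(v, 6)
                                 for f, v in res.null_likelihoods.items()},
        }
    report["lod"] = lod_report

    # Stage 5: pairwise relatedness (founder-frequency based).
    pairs = pairwise_matrix(g, pedigree=pedigrees)
    pairs.to_csv(out_dir / "relatedness.tsv", sep="\t", index=False,
                 float_format="%.6f")
    fam_of = {m.id: ped.family_id for ped in pedigrees for m in ped}
    cross = pairs[[fam_of[i] != fam_of[j] for i, j in zip(pairs.I, pairs.J)]]
    parent_child = []
    for ped in pedigrees:
        for m in ped:
            parents = ped.parents_of(m.id)
            if parents:
                parent_child.extend({m.id, p} for p in parents)
    pc_mask = [({i, j} in parent_child) for i, j in zip(pairs.I, pairs.J)]
    pc = pairs[pc_mask]
    report["relatedness"] = {
        "max_cross_family_pi_hat":
            round(float(cross.PI_HAT.max()), 4) if len(cross) else None,
        "mean_parent_child_pi_hat":
            round(float(pc.PI_HAT.mean()), 4) if len(pc) else None,
        "n_pairs": int(len(pairs)),
    }

    # Stage 6: conserved haplotype core around each final candidate.
    cores = {}
    for key in candidates:
        chrom, pos = key.split(":")[:2]
        carriers = [m.id for fid in survivors[key]
                    for m in next(p for p in pedigrees
                                  if p.family_id == fid).affected]
        try:
            core = core_interval(g, (chrom, int(pos)), carriers)
            cores[key] = {"chrom": core.chrom, "start": core.start,
                          "end": core.end, "n_snps": core.n_snps,
                          "length_bp": core.length_bp}
        except HapcoreError as exc:  # pragma: no cover - defensive
            cores[key] = {"error": str(exc)}
    report["haplotype_core"] = cores

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


# -- default synthetic fixture ----------------------------------------------

@dataclass
class FixtureInfo:
    """Paths and ground truth of a generated two-family fixture."""

    paths: dict[str, Path]
    causal_key: str
    causal: tuple[str, int]
    pedigrees: list[Pedigree]
    genotypes: GenotypeMatrix
    tracts: list
    gmap: GeneticMap
    founder_freqs: np.ndarray


def first_cousin_sibship(family_id: str, n_affected: int = 2,
                         n_unaffected: int = 2, prefix: str = ""
                         ) -> tuple[Pedigree, list[str]]:
    """A nuclear sibship whose parents are first cousins (12 members).

    Great-grandparents A1 x A2 have two children (B1, B3) who marry
    unrelated founders (B2, B4); their children C1 and C2 are first cousins
    and parent the sibship D1..Dn, of which the first ``n_affected`` are
    affected.  Returns the pedigree and the affected ids.
    """
    from .pedigree import Individual, Sex

    def ind(iid, father=None, mother=None, sex=Sex.UNKNOWN,
            pheno=Phenotype.UNAFFECTED):
        return Individual(prefix + iid,
                          prefix + father if father else None,
                          prefix + mother if mother else None, sex, pheno)

    members = [
        ind("A1", sex=Sex.MALE), ind("A2", sex=Sex.FEMALE),
        ind("B1", "A1", "A2", Sex.MALE), ind("B2", sex=Sex.FEMALE),
        ind("B3", "A1", "A2", Sex.FEMALE), ind("B4", sex=Sex.MALE),
        ind("C1", "B1", "B2", Sex.MALE), ind("C2", "B4", "B3", Sex.FEMALE),
    ]
    affected_ids = []
    for k in range(n_affected + n_unaffected):
        aff = k < n_affected
        iid = f"D{k + 1}"
        members.append(ind(iid, "C1", "C2",
                           Sex.MALE if k % 2 == 0 else Sex.FEMALE,
                           Phenotype.AFFECTED if aff else Phenotype.UNAFFECTED))
        if aff:
            affected_ids.append(prefix + iid)
    return Pedigree(family_id, members), affected_ids


def build_default_fixture(seed: int, out_dir: str | Path,
                          n_chromosomes: int = 2,
                          chrom_length_bp: int = 100_000_000,
                          variants_per_chromosome: int = 10_000,
                          cm_per_mb: float = 1.0,
                          n_families: int = 2,
                          genotype_error_rate: float = 0.0) -> FixtureInfo:
    """Generate the study-shaped two-family fixture and write its files.

    Two first-cousin-loop families, each with two affected and two
    unaffected siblings, independent founder sets, and one shared causal
    variant planted homozygous-and-autozygous in every affected sibling
    (founder alt frequency 0.5 at the causal site so rejection sampling is
    tractable; background founder frequencies Uniform(0.05, 0.95)).
    """
    gmap = GeneticMap.uniform(n_chromosomes, chrom_length_bp, cm_per_mb,
                              variants_per_chromosome)
    rng = np.random.default_rng([seed, 7])
    freqs = rng.uniform(0.05, 0.95, gmap.n_variants)
    causal_idx = variants_per_chromosome // 2  # mid-chromosome "1"
    causal = ("1", int(gmap.positions["1"][causal_idx]))
    freqs[causal_idx] = 0.5

    pedigrees, mats, tracts = [], [], []
    for k in range(n_families):
        fid = f"F{k + 1}"
        ped, affected = first_cousin_sibship(fid, prefix=f"{fid}_")
        gk, tk = plant_causal_variant(ped, gmap, freqs, affected, causal,
                                      seed=int(np.random.default_rng(
                                          [seed, 11, k]).integers(2 ** 31)),
                                      genotype_error_rate=genotype_error_rate)
        pedigrees.append(ped)
        mats.append(gk)
        tracts.extend(tk)

    samples = [s for m in mats for s in m.samples]
    codes = np.vstack([m.codes for m in mats])
    origins = np.concatenate([m.origins for m in mats], axis=0)
    g = GenotypeMatrix(samples, gmap.variant_table(), codes, origins)
    annotations = simulate_annotations(g, causal, seed=int(
        np.random.default_rng([seed, 13]).integers(2 ** 31)))

    paths = az_io.write_fixture(g, pedigrees, annotations, out_dir,
                                tracts=tracts)
    ci = g.variant_index(*causal)
    return FixtureInfo(paths, g.variant_key(ci), causal, pedigrees, g,
                       tracts, gmap, freqs)


def run_default_fixture(seed: int, out_dir: str | Path,
                        **fixture_kwargs) -> tuple[dict, FixtureInfo]:
    """Generate the default fixture under ``out_dir`` and run the pipeline."""
    out_dir = Path(out_dir)
    fixture = build_default_fixture(seed, out_dir / "fixture", **fixture_kwargs)
    config = PipelineConfig(
        vcf=fixture.paths["vcf"], ped=fixture.paths["ped"],
        annotations=fixture.paths["annotations"],
        out_dir=out_dir / "results", seed=seed)
    return run_pipeline(config), fixture


def configure_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)
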