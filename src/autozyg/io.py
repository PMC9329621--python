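"""File I/O: VCF (GT-only), annotation TSV, tract/region BED, fixture bundles.

VCF is written as plain v4.2 text with a single GT FORMAT field and read
back through cyvcf2; BED files are 0-based half-open.  PED I/O lives in
:mod:`autozyg.pedigree`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .pedigree import Pedigree, write_ped
from .simulate import ANNOTATION_COLUMNS, AutozygosityTract, GenotypeMatrix

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_CYVCF2_TO_CODE = np.array([0, 1, -1, 2], dtype=np.int8)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> Path:
    """Write a GT-only VCF v4.2 with contig headers."""
    path = Path(path)
    contigs = list(dict.fromkeys(g.variants["CHROM"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=autozyg\n")
        for chrom in contigs:
            length = int(g.variants.loc[g.variants["CHROM"] == chrom, "POS"].max())
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for k, row in enumerate(g.variants.itertuples(index=False)):
            gts = "\t".join(_GT_STRING[int(c)] for c in g.codes[:, k])
            fh.write(f"{row.CHROM}\t{row.POS}\t.\t{row.REF}\t{row.ALT}\t.\tPASS"
                     f"\t.\tGT\t{gts}\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read genotypes (GT field only) from a VCF into a GenotypeMatrix."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[tuple[str, int, str, str]] = []
    codes: list[np.ndarray] = []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rows.append((var.CHROM, var.POS, var.REF, alt))
        codes.append(_CYVCF2_TO_CODE[var.gt_types])
    vcf.close()
    variants = pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT"])
    mat = np.column_stack(codes) if codes else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(samples, variants, mat)


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    annotations[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return df


def write_tracts_bed(tracts: Iterable[AutozygosityTract], path: str | Path) -> Path:
    """Tracts as 0-based half-open BED with the sample id in column 4."""
    path = Path(path)
    with open(path, "w") as fh:
        for t in sorted(tracts, key=lambda t: (t.sample, t.chrom, t.start)):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.sample}\n")
    return path


def read_tracts_bed(path: str | Path) -> list[AutozygosityTract]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, sample = line.split()[:4]
            out.append(AutozygosityTract(sample, chrom, int(start), int(end)))
    return out


def write_regions_bed(regions: Sequence[tuple[str, int, int]],
                      path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    return path


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start), int(end)))
    return out


def write_fixture(g: GenotypeMatrix, pedigrees: Sequence[Pedigree],
                  annotations: pd.DataFrame,
                  out_dir: str | Path,
                  tracts: Iterable[AutozygosityTract] | None = None
                  ) -> dict[str, Path]:
    """Write a complete analysis input bundle (VCF + PED + TSV [+ BED]).

    Round-trips losslessly through :func:`read_vcf`,
    :func:`autozyg.pedigree.read_ped`, :func:`read_annotations` and
    :func:`read_tracts_bed`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(g, out_dir / "cohort.vcf"),
        "ped": write_ped(pedigrees, out_dir / "cohort.ped"),
        "annotations": write_annotations(annotations, out_dir / "annotations.tsv"),
    }
    if tracts is not None:
        paths["tracts"] = write_tracts_bed(tracts, out_dir / "true_tracts.bed")
    return paths
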