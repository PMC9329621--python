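"""Variant prioritization funnel for homozygosity-mapped regions.

Annotated variants restricted to the shared homozygous regions are pushed
through a fixed stage order: (1) homozygous-alt in every affected sample,
(2) population MAF at most a threshold, (3) CADD deleteriousness at least a
threshold, (4) functional class in an allowed set (exonic / splice).  The
per-stage surviving counts are the discovery funnel a study reports.

Thresholds are inclusive by default (MAF <= max, CADD >= min); a strict
mode is exposed.  Missing MAF is treated as 0 (absent from population
databases means rare) and missing CADD as failing the CADD stage; both
policies are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

VARIANT_CLASSES = frozenset({"exonic", "splice", "other"})


class FunnelError(ValueError):
    pass


@dataclass
class FunnelResult:
    """Ordered (stage name, surviving count) pairs plus the survivor table."""

    stages: list[tuple[str, int]]
    survivors: pd.DataFrame

    @property
    def counts(self) -> list[int]:
        return [n for _, n in self.stages]


def restrict_to_regions(variants: pd.DataFrame,
                        regions: Sequence[tuple[str, int, int]]) -> pd.DataFrame:
    """Keep variants whose 1-based POS falls inside any half-open region.

    Regions are (chrom, start, end) on the same 1-based coordinate system,
    half-open: a variant at ``start`` is kept, one at ``end`` is dropped.
    """
    if not len(variants):
        return variants.copy()
    keep = np.zeros(len(variants), dtype=bool)
    chroms = variants["CHROM"].astype(str).to_numpy()
    pos = variants["POS"].to_numpy()
    for chrom, start, end in regions:
        keep |= (chroms == str(chrom)) & (pos >= start) & (pos < end)
    return variants.loc[keep].copy()


def regions_from_bed(bed: Sequence[tuple[str, int, int]]
                     ) -> list[tuple[str, int, int]]:
    """Convert 0-based half-open BED intervals to 1-based half-open regions."""
    return [(chrom, start + 1, end + 1) for chrom, start, end in bed]


def filter_funnel(variants: pd.DataFrame,
                  g: GenotypeMatrix,
                  affected: Sequence[str],
                  maf_max: float = 0.001,
                  cadd_min: float = 15.0,
                  classes: Sequence[str] = ("exonic", "splice"),
                  *,
                  inclusive: bool = True,
                  missing_maf_is_rare: bool = True,
                  missing_cadd_fails: bool = True) -> FunnelResult:
    """Apply the four filtering stages and report per-stage counts.

    ``variants`` must already be restricted to the candidate regions (see
    :func:`restrict_to_regions`); rows are matched to ``g`` by (CHROM, POS).
    Counts are non-increasing and permutation-invariant.
    """
    if maf_max < 0 or cadd_min < 0:
        raise FunnelError("thresholds must be non-negative")
    bad = set(classes) - VARIANT_CLASSES
    if bad:
        raise FunnelError(f"unknown variant classes {sorted(bad)}")

    df = variants.copy()
    stages: list[tuple[str, int]] = [("input", len(df))]

    hom_rows = [
        all(g.genotype(s, row.CHROM, row.POS) == 2 for s in affected)
        for row in df.itertuples(index=False)
    ]
    df = df.loc[np.asarray(hom_rows, dtype=bool)] if len(df) else df
    stages.append(("hom_in_affected", len(df)))

    maf = df["MAF"].astype(float)
    if missing_maf_is_rare:
        maf = maf.fillna(0.0)
    keep = (maf <= maf_max) if inclusive else (maf < maf_max)
    keep &= maf.notna()
    df = df.loc[keep]
    stages.append(("maf", len(df)))

    cadd = df["CADD"].astype(float)
    keep = (cadd >= cadd_min) if inclusive else (cadd > cadd_min)
    if missing_cadd_fails:
        keep &= cadd.notna()
    else:
        keep |= cadd.isna()
    df = df.loc[keep]
    stages.append(("cadd", len(df)))

    df = df.loc[df["CLASS"].isin(set(classes))]
    stages.append(("class", len(df)))

    return FunnelResult(stages, df.reset_index(drop=True))
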