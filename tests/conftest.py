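"""Shared fixtures: small pedigrees, the default synthetic cohort run, and
the published segregation genotypes of the four candidate genes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import autozyg as az
from autozyg.pedigree import Individual, Pedigree, Phenotype, Sex


@pytest.fixture(scope="session")
def cousin_family() -> tuple[Pedigree, list[str]]:
    return az.first_cousin_sibship("F1", prefix="F1_")


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One end-to-end pipeline run on the default two-family fixture."""
    out = tmp_path_factory.mktemp("default_run")
    report, fixture = az.run_default_fixture(seed=1, out_dir=out)
    return report, fixture, out


def single_sample_matrix(codes: list[int], spacing: int = 1000,
                         positions: list[int] | None = None,
                         sample: str = "S1") -> az.GenotypeMatrix:
    """A one-sample, one-chromosome GenotypeMatrix from explicit codes."""
    n = len(codes)
    pos = positions if positions is not None \
        else [spacing * (k + 1) for k in range(n)]
    variants = pd.DataFrame({
        "CHROM": ["1"] * n,
        "POS": pos,
        "REF": ["A"] * n,
        "ALT": ["G"] * n,
    })
    return az.GenotypeMatrix([sample], variants,
                             np.asarray([codes], dtype=np.int8))


def matrix_from_codes(samples: list[str], codes: np.ndarray,
                      positions: list[int] | None = None,
                      chrom: str = "1") -> az.GenotypeMatrix:
    codes = np.asarray(codes, dtype=np.int8)
    n = codes.shape[1]
    pos = positions if positions is not None else [1000 * (k + 1)
                                                   for k in range(n)]
    variants = pd.DataFrame({"CHROM": [chrom] * n, "POS": pos,
                             "REF": ["A"] * n, "ALT": ["G"] * n})
    return az.GenotypeMatrix(samples, variants, codes)


# -- published two-family segregation data ----------------------------------

def _family_one() -> Pedigree:
    mk = Individual
    return Pedigree("FAM1", [
        mk("III-2", sex=Sex.FEMALE, phenotype=Phenotype.UNAFFECTED),
        mk("IV-1", sex=Sex.MALE, phenotype=Phenotype.UNAFFECTED),
        mk("V-1", "IV-1", "III-2", Sex.FEMALE, Phenotype.UNAFFECTED),
        mk("V-2", "IV-1", "III-2", Sex.MALE, Phenotype.AFFECTED),
        mk("V-4", "IV-1", "III-2", Sex.MALE, Phenotype.AFFECTED),
        mk("V-5", "IV-1", "III-2", Sex.MALE, Phenotype.UNAFFECTED),
    ])


def _family_two() -> Pedigree:
    mk = Individual
    return Pedigree("FAM2", [
        mk("II-10", sex=Sex.MALE, phenotype=Phenotype.UNAFFECTED),
        mk("II-11", sex=Sex.FEMALE, phenotype=Phenotype.UNAFFECTED),
        mk("III-2", "II-10", "II-11", Sex.MALE, Phenotype.UNAFFECTED),
        mk("III-4", "II-10", "II-11", Sex.FEMALE, Phenotype.AFFECTED),
        mk("III-5", "II-10", "II-11", Sex.FEMALE, Phenotype.AFFECTED),
        mk("III-6", "II-10", "II-11", Sex.FEMALE, Phenotype.UNAFFECTED),
    ])


#: Sanger/panel genotype codes for the four candidate variants in the two
#: consanguineous study families (2 = hom alt, 1 = het, 0 = wild type).
TABLE_GENOTYPES = {
    "FAM1": {
        "CNTNAP2": {"V-2": 2, "V-4": 2, "III-2": 1, "IV-1": 1,
                    "V-1": 1, "V-5": 1},
        "ALG6": {"V-2": 2, "V-4": 2, "III-2": 1, "IV-1": 1,
                 "V-1": 2, "V-5": 1},
        "RBM20": {"V-2": 2, "V-4": 2, "III-2": 1, "IV-1": 1,
                  "V-1": 1, "V-5": 1},
        "PDZD7": {"V-2": 2, "V-4": 2, "III-2": 1, "IV-1": 1,
                  "V-1": 1, "V-5": 1},
    },
    "FAM2": {
        "CNTNAP2": {"III-4": 2, "III-5": 2, "II-10": 1, "II-11": 1,
                    "III-2": 0, "III-6": 0},
        "ALG6": {s: 0 for s in ("III-4", "III-5", "II-10", "II-11",
                                "III-2", "III-6")},
        "RBM20": {s: 0 for s in ("III-4", "III-5", "II-10", "II-11",
                                 "III-2", "III-6")},
        "PDZD7": {s: 0 for s in ("III-4", "III-5", "II-10", "II-11",
                                 "III-2", "III-6")},
    },
}


@pytest.fixture(scope="session")
def study_families() -> dict[str, Pedigree]:
    return {"FAM1": _family_one(), "FAM2": _family_two()}
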