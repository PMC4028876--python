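import numpy as np
import pytest

from haplocombine.datamodel import (
    CohortData,
    GenotypeMatrix,
    Haplotype,
    TrioRecord,
)


def H(s: str) -> Haplotype:
    return Haplotype.from_string(s)


@pytest.fixture
def two_snp_haps():
    return [H("1-1"), H("1-2"), H("2-1"), H("2-2")]


def make_genotypes(geno, phenotype=None, prefix="s"):
    geno = np.asarray(geno)
    n = geno.shape[0]
    if phenotype is None:
        phenotype = np.zeros(n, dtype=int)
    return GenotypeMatrix(
        sample_ids=[f"{prefix}{i + 1}" for i in range(n)],
        geno=geno,
        phenotype=np.asarray(phenotype),
        snp_ids=[f"snp{j + 1}" for j in range(geno.shape[1])],
    )


@pytest.fixture
def small_cohort_files(tmp_path):
    """PED/MAP with 2 trios + 3 unrelated cases + 3 unrelated controls, q=2."""
    map_text = "1\tsnp1\t0\t1\n1\tsnp2\t0\t2\n"
    ped_rows = [
        # family 1: father 1-1/2-1, mother 1-1/1-1, affected child
        "F1 dad1 0 0 1 1  1 2 1 1",
        "F1 mom1 0 0 2 1  1 1 1 1",
        "F1 kid1 dad1 mom1 1 2  1 2 1 1",
        # family 2: fully heterozygous trio
        "F2 dad2 0 0 1 0  1 2 1 2",
        "F2 mom2 0 0 2 0  1 2 1 2",
        "F2 kid2 dad2 mom2 2 2  1 2 1 2",
        # unrelated cases
        "U1 c1 0 0 1 2  2 2 1 1",
        "U2 c2 0 0 2 2  1 2 1 2",
        "U3 c3 0 0 1 2  1 1 2 2",
        # unrelated controls
        "U4 u1 0 0 1 1  1 1 1 1",
        "U5 u2 0 0 2 1  1 2 1 1",
        "U6 u3 0 0 1 1  2 2 2 2",
    ]
    ped = tmp_path / "fixture.ped"
    mp = tmp_path / "fixture.map"
    ped.write_text("\n".join(ped_rows) + "\n")
    mp.write_text(map_text)
    return ped, mp
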