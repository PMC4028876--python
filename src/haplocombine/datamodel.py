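"""Core data containers and PLINK-text pedigree I/O.

Genotypes are stored as counts of allele "2" (0, 1 or 2 copies) at each of
``q`` biallelic SNPs.  A cohort mixes two sampling designs: case-parent
trios (father, mother, affected child) and unrelated case-control samples.
Missing genotypes are rejected: the downstream phasing and association
machinery assumes complete data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Haplotype",
    "GenotypeMatrix",
    "TrioRecord",
    "CohortData",
    "PedigreeError",
    "read_ped",
    "write_ped",
    "split_sources",
]

PHENO_UNKNOWN = -1


class PedigreeError(ValueError):
    """Malformed or internally inconsistent pedigree input."""


@dataclass(frozen=True, order=True)
class Haplotype:
    """An ordered run of alleles (coded 1/2) across q neighbouring SNPs."""

    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if not all(a in (1, 2) for a in self.alleles):
            raise ValueError(f"alleles must be coded 1/2, got {self.alleles}")

    @property
    def q(self) -> int:
        return len(self.alleles)

    @property
    def dosage(self) -> tuple[int, ...]:
        """Copies of allele 2 contributed at each SNP (0 or 1)."""
        return tuple(a - 1 for a in self.alleles)

    @classmethod
    def from_string(cls, s: str) -> "Haplotype":
        return cls(tuple(int(tok) for tok in s.split("-")))

    def __str__(self) -> str:
        return "-".join(str(a) for a in self.alleles)

    def __repr__(self) -> str:
        return f"Haplotype({self})"


@dataclass
class GenotypeMatrix:
    """Unphased genotypes for a set of samples.

    ``geno[i, j]`` is the number of copies of allele 2 carried by sample
    ``i`` at SNP ``j``.  ``phenotype`` is 1 (affected) / 0 (unaffected) /
    -1 (unknown, allowed only for trio parents).
    """

    sample_ids: list[str]
    geno: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.geno.ndim != 2:
            raise ValueError("geno must be 2-D (samples x SNPs)")
        if not np.isin(self.geno, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1 or 2")
        if len(self.sample_ids) != self.geno.shape[0]:
            raise ValueError("sample_ids length does not match geno rows")
        if len(self.snp_ids) != self.geno.shape[1]:
            raise ValueError("snp_ids length does not match geno columns")
        if self.phenotype.shape != (self.geno.shape[0],):
            raise ValueError("phenotype length does not match geno rows")

    @property
    def n_samples(self) -> int:
        return self.geno.shape[0]

    @property
    def q(self) -> int:
        return self.geno.shape[1]

    def subset(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = list(rows)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            geno=self.geno[rows],
            phenotype=self.phenotype[rows],
            snp_ids=list(self.snp_ids),
        )


@dataclass(frozen=True)
class TrioRecord:
    """Row indices of one father/mother/affected-child triple."""

    father_row: int
    mother_row: int
    child_row: int


@dataclass
class CohortData:
    """A genotyped cohort partitioned into trios and unrelated samples."""

    genotypes: GenotypeMatrix
    trios: list[TrioRecord] = field(default_factory=list)
    unrelated_case_idx: list[int] = field(default_factory=list)
    unrelated_control_idx: list[int] = field(default_factory=list)

    @property
    def n1(self) -> int:
        return len(self.trios)

    @property
    def n2(self) -> int:
        return len(self.unrelated_case_idx)

    @property
    def n3(self) -> int:
        return len(self.unrelated_control_idx)

    @property
    def q(self) -> int:
        return self.genotypes.q

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for t in self.trios:
            for r in (t.father_row, t.mother_row, t.child_row):
                if r in seen:
                    raise PedigreeError(f"sample row {r} assigned to multiple roles")
                seen.add(r)
        for r in list(self.unrelated_case_idx) + list(self.unrelated_control_idx):
            if r in seen:
                raise PedigreeError(f"sample row {r} assigned to multiple roles")
            seen.add(r)


def _transmissible(gf: int, gm: int, gc: int) -> bool:
    """Can parents with allele-2 counts gf, gm produce a child with gc?"""
    poss = {0: (0,), 1: (0, 1), 2: (1,)}
    return any(af + am == gc for af in poss[gf] for am in poss[gm])


def check_mendelian(geno: np.ndarray, snp_ids: Sequence[str],
                    father: int, mother: int, child: int,
                    child_id: str = "?") -> None:
    """Raise :class:`PedigreeError` at the first impossible transmission."""
    for j in range(geno.shape[1]):
        if not _transmissible(int(geno[father, j]), int(geno[mother, j]),
                              int(geno[child, j])):
            raise PedigreeError(
                f"Mendelian inconsistency for child {child_id} at SNP "
                f"{snp_ids[j]}: father={geno[father, j]}, "
                f"mother={geno[mother, j]}, child={geno[child, j]}"
            )


def read_ped(ped_path: str | Path, map_path: str | Path) -> CohortData:
    """Read whitespace-delimited PLINK-text PED/MAP files.

    Samples whose parent IDs are both non-zero and present in the file
    become trio children (and must be affected); samples with parent IDs
    "0" are unrelated cases/controls according to their phenotype
    (PED coding: 1 = unaffected, 2 = affected).
    """
    snp_ids: list[str] = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        toks = line.split()
        if len(toks) < 2:
            raise PedigreeError(f"{map_path}:{ln}: expected >=2 columns")
        snp_ids.append(toks[1])
    q = len(snp_ids)
    if q == 0:
        raise PedigreeError(f"{map_path}: no markers")

    sample_ids: list[str] = []
    parents: list[tuple[str, str]] = []
    fids: list[str] = []
    genos: list[list[int]] = []
    phenos: list[int] = []
    key_to_row: dict[tuple[str, str], int] = {}

    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        toks = line.split()
        if len(toks) != 6 + 2 * q:
            raise PedigreeError(
                f"{ped_path}:{ln}: expected {6 + 2 * q} columns, got {len(toks)}"
            )
        fid, iid, pat, mat, _sex, pheno = toks[:6]
        alleles = toks[6:]
        row = []
        for j in range(q):
            a1, a2 = alleles[2 * j], alleles[2 * j + 1]
            for a in (a1, a2):
                if a not in ("1", "2"):
                    raise PedigreeError(
                        f"sample {iid}: allele '{a}' at SNP {snp_ids[j]} "
                        "(only codes 1/2 are supported; 0/missing is rejected)"
                    )
            row.append((int(a1) - 1) + (int(a2) - 1))
        if pheno == "2":
            ph = 1
        elif pheno == "1":
            ph = 0
        else:
            ph = PHENO_UNKNOWN
        key = (fid, iid)
        if key in key_to_row:
            raise PedigreeError(f"duplicate sample {fid}/{iid}")
        key_to_row[key] = len(sample_ids)
        sample_ids.append(iid)
        fids.append(fid)
        parents.append((pat, mat))
        genos.append(row)
        phenos.append(ph)

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        geno=np.array(genos, dtype=np.int8),
        phenotype=np.array(phenos, dtype=np.int8),
        snp_ids=snp_ids,
    )

    trios: list[TrioRecord] = []
    cases: list[int] = []
    controls: list[int] = []
    parent_rows: set[int] = set()
    child_rows: set[int] = set()
    for i, (pat, mat) in enumerate(parents):
        if pat == "0" and mat == "0":
            continue
        fkey, mkey = (fids[i], pat), (fids[i], mat)
        if fkey not in key_to_row or mkey not in key_to_row:
            raise PedigreeError(
                f"trio offspring {sample_ids[i]}: parent record "
                f"{pat if fkey not in key_to_row else mat} missing from PED"
            )
        if phenos[i] != 1:
            raise PedigreeError(
                f"trio offspring {sample_ids[i]} is not affected; only "
                "affected-proband trios are supported"
            )
        f_row, m_row = key_to_row[fkey], key_to_row[mkey]
        check_mendelian(gm.geno, snp_ids, f_row, m_row, i, sample_ids[i])
        trios.append(TrioRecord(f_row, m_row, i))
        parent_rows.update((f_row, m_row))
        child_rows.add(i)

    for i, (pat, mat) in enumerate(parents):
        if i in parent_rows or i in child_rows:
            continue
        if pat == "0" and mat == "0":
            if phenos[i] == 1:
                cases.append(i)
            elif phenos[i] == 0:
                controls.append(i)
            else:
                raise PedigreeError(
                    f"unrelated sample {sample_ids[i]} has missing phenotype"
                )

    return CohortData(genotypes=gm, trios=trios,
                      unrelated_case_idx=cases,
                      unrelated_control_idx=controls)


def write_ped(cohort: CohortData, ped_path: str | Path,
              map_path: str | Path, chrom: str = "1") -> None:
    """Write a cohort back to PLINK-text PED/MAP (inverse of read_ped)."""
    gm = cohort.genotypes
    with open(map_path, "w") as fh:
        for j, sid in enumerate(gm.snp_ids):
            fh.write(f"{chrom}\t{sid}\t0\t{j + 1}\n")

    def geno_tokens(row: int) -> list[str]:
        out = []
        for g in gm.geno[row]:
            a = {0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2")}[int(g)]
            out.extend(a)
        return out

    def pheno_code(row: int) -> str:
        return {1: "2", 0: "1", PHENO_UNKNOWN: "0"}[int(gm.phenotype[row])]

    with open(ped_path, "w") as fh:
        for k, t in enumerate(cohort.trios, 1):
            fid = f"F{k}"
            fa, mo, ch = (gm.sample_ids[t.father_row],
                          gm.sample_ids[t.mother_row],
                          gm.sample_ids[t.child_row])
            for row, iid, pat, mat, sex in (
                (t.father_row, fa, "0", "0", "1"),
                (t.mother_row, mo, "0", "0", "2"),
                (t.child_row, ch, fa, mo, "0"),
            ):
                toks = [fid, iid, pat, mat, sex, pheno_code(row)] + geno_tokens(row)
                fh.write("\t".join(toks) + "\n")
        for row in list(cohort.unrelated_case_idx) + list(cohort.unrelated_control_idx):
            iid = gm.sample_ids[row]
            toks = [f"U{iid}", iid, "0", "0", "0", pheno_code(row)] + geno_tokens(row)
            fh.write("\t".join(toks) + "\n")


def split_sources(cohort: CohortData) -> tuple[CohortData, CohortData]:
    """Split a cohort into its trio subset and its case-control subset."""
    trio_rows: list[int] = []
    for t in cohort.trios:
        trio_rows.extend((t.father_row, t.mother_row, t.child_row))
    remap = {old: new for new, old in enumerate(trio_rows)}
    trio_part = CohortData(
        genotypes=cohort.genotypes.subset(trio_rows),
        trios=[TrioRecord(remap[t.father_row], remap[t.mother_row],
                          remap[t.child_row]) for t in cohort.trios],
    )
    cc_rows = list(cohort.unrelated_case_idx) + list(cohort.unrelated_control_idx)
    cc_remap = {old: new for new, old in enumerate(cc_rows)}
    cc_part = CohortData(
        genotypes=cohort.genotypes.subset(cc_rows),
        unrelated_case_idx=[cc_remap[i] for i in cohort.unrelated_case_idx],
        unrelated_control_idx=[cc_remap[i] for i in cohort.unrelated_control_idx],
    )
    return trio_part, cc_part
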