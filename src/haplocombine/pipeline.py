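"""End-to-end convenience workflow: cohort in, combined fit out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import (
    HGLMFit,
    design_from_matrices,
    fit_hglm,
    select_reference,
)
from .datamodel import CohortData, Haplotype
from .phasing import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    HaplotypeFrequencySet,
    em_trios,
    em_unrelated,
    extend_to_space,
    trio_weighted_count_matrices,
    union_space,
    weighted_count_matrix,
)

__all__ = ["CohortCounts", "cohort_weighted_counts", "combined_analysis"]


@dataclass
class CohortCounts:
    """Weighted-count matrices of a cohort over one shared haplotype space."""

    space: list[Haplotype]
    trio_case: np.ndarray          # (n1, H)
    trio_pseudo: np.ndarray        # (n1, H)
    cc_counts: np.ndarray          # (n2+n3, H)
    cc_pheno: np.ndarray
    cc_sample_ids: list[str]
    trio_child_ids: list[str]
    trio_hf: HaplotypeFrequencySet | None
    cc_hf: HaplotypeFrequencySet | None

    @property
    def pooled_freqs(self) -> dict[Haplotype, float]:
        M = np.vstack([self.trio_case, self.trio_pseudo, self.cc_counts])
        return dict(zip(self.space, M.mean(axis=0) / 2.0))

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(matrix, source labels) over trio rows then unrelated rows."""
        H = np.vstack([self.trio_case, self.trio_pseudo, self.cc_counts])
        grp = np.array(["trio"] * (len(self.trio_case) + len(self.trio_pseudo))
                       + ["case-control"] * len(self.cc_counts))
        return H, grp


def cohort_weighted_counts(cohort: CohortData, tol: float = DEFAULT_TOL,
                           max_iter: int = DEFAULT_MAX_ITER) -> CohortCounts:
    """Source-wise EM frequency estimation and weighted-count conversion."""
    gm = cohort.genotypes
    thf = uhf = None
    spaces = []
    if cohort.trios:
        thf = em_trios(gm, cohort.trios, tol=tol, max_iter=max_iter)
        spaces.append(thf.haplotypes)
    cc = None
    if cohort.n2 + cohort.n3:
        cc = gm.subset(list(cohort.unrelated_case_idx)
                       + list(cohort.unrelated_control_idx))
        uhf = em_unrelated(cc, tol=tol, max_iter=max_iter)
        spaces.append(uhf.haplotypes)
    if not spaces:
        raise ValueError("cohort contains no samples")
    space = union_space(*spaces)
    H = len(space)
    if thf is not None:
        tc, tp = trio_weighted_count_matrices(gm, cohort.trios,
                                              extend_to_space(thf, space))
        child_ids = [gm.sample_ids[t.child_row] for t in cohort.trios]
    else:
        tc = tp = np.zeros((0, H))
        child_ids = []
    if uhf is not None:
        ccm = weighted_count_matrix(cc, extend_to_space(uhf, space))
        cc_pheno = cc.phenotype.astype(float)
        cc_ids = list(cc.sample_ids)
    else:
        ccm = np.zeros((0, H))
        cc_pheno = np.zeros(0)
        cc_ids = []
    return CohortCounts(space=space, trio_case=tc, trio_pseudo=tp,
                        cc_counts=ccm, cc_pheno=cc_pheno,
                        cc_sample_ids=cc_ids, trio_child_ids=child_ids,
                        trio_hf=thf, cc_hf=uhf)


def combined_analysis(cohort: CohortData,
                      reference: Haplotype | str | None = None,
                      rare_threshold: float = 0.0,
                      global_test: str = "lrt",
                      tol: float = DEFAULT_TOL,
                      max_iter: int = DEFAULT_MAX_ITER,
                      ) -> tuple[HGLMFit, CohortCounts]:
    """Phase, build the combined design and fit the HGLM in one call."""
    counts = cohort_weighted_counts(cohort, tol=tol, max_iter=max_iter)
    if reference is None or reference == "auto":
        reference = select_reference(counts.pooled_freqs)
    elif isinstance(reference, str):
        reference = Haplotype.from_string(reference)
    design = design_from_matrices(counts.trio_case, counts.trio_pseudo,
                                  counts.cc_counts, counts.cc_pheno,
                                  counts.space, reference, rare_threshold)
    return fit_hglm(design, global_test=global_test), counts
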