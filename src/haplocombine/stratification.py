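"""Cluster-corrected combined analysis (M-HGLM).

Population stratification among the unrelated case-control samples makes
the plain combined fit anti-conservative.  The correction clusters the
mixed case-control samples on normalized genotypes (Ward's method or
K-means), re-estimates haplotype frequencies and weighted counts within
each inferred subgroup, and refits the combined model with
cluster-membership main effects absorbing the subgroup differences in
baseline disease odds.  Trios are never clustered: the within-family
pseudo-control construction is already robust to stratification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .association import CombinedDesign, HGLMFit, design_from_matrices, fit_hglm
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

__all__ = ["ClusterAssignment", "normalize_genotypes", "cluster_samples",
           "fit_mhglm", "MHGLMResult"]


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # cluster id in 1..K per unrelated sample
    K: int
    method: str                 # "ward" | "kmeans"
    seed: int | None
    inertia: float | None = None       # K-means within-cluster SSE
    merge_heights: np.ndarray | None = None  # Ward dendrogram heights


@dataclass
class MHGLMResult:
    fit: HGLMFit
    design: CombinedDesign
    clusters: ClusterAssignment
    cluster_hfs: list[HaplotypeFrequencySet]
    trio_hf: HaplotypeFrequencySet


def normalize_genotypes(G: np.ndarray) -> np.ndarray:
    """Column-standardize genotypes (sample sd, n-1); constant columns -> 0."""
    G = np.asarray(G, dtype=float)
    if G.shape[0] < 2:
        raise ValueError("need at least two samples to normalize")
    mu = G.mean(axis=0)
    sd = G.std(axis=0, ddof=1)
    Z = G - mu
    nz = sd > 0
    Z[:, nz] /= sd[nz]
    Z[:, ~nz] = 0.0
    return Z


def cluster_samples(Z: np.ndarray, method: str = "kmeans", K: int = 2,
                    seed: int | None = 0, n_init: int = 10,
                    ) -> ClusterAssignment:
    """Partition samples into K groups on Euclidean distance.

    Ward's agglomerative method (Ward.D2 dialect: merge minimizing the
    increase in total within-cluster sum of squares) is deterministic;
    K-means runs ``n_init`` seeded restarts and keeps the best inertia.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must be in 1..{n}")
    if K == 1:
        return ClusterAssignment(np.ones(n, dtype=int), 1, method, seed)
    if method == "ward":
        link = linkage(Z, method="ward")
        labels = fcluster(link, t=K, criterion="maxclust")
        return ClusterAssignment(labels.astype(int), K, "ward", seed,
                                 merge_heights=link[:, 2])
    if method == "kmeans":
        km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
        labels = km.fit_predict(Z) + 1
        return ClusterAssignment(labels.astype(int), K, "kmeans", seed,
                                 inertia=float(km.inertia_))
    raise ValueError("method must be 'ward' or 'kmeans'")


def fit_mhglm(cohort: CohortData, method: str = "kmeans", K: int = 2,
              seed: int | None = 0, tol: float = DEFAULT_TOL,
              max_iter: int = DEFAULT_MAX_ITER,
              rare_threshold: float = 0.0,
              reference: Haplotype | None = None,
              cluster_main_effects: bool = True,
              global_test: str = "lrt") -> MHGLMResult:
    """Cluster-corrected combined haplotype fit.

    Pipeline: normalize unrelated genotypes -> cluster -> per-cluster EM
    and weighted counts -> trio EM and transmission counts on all trios
    -> stack over the union haplotype space -> logistic fit.  With
    ``cluster_main_effects`` (default) the design gains one indicator
    column per cluster beyond the first, so inferred-subgroup baseline
    odds are absorbed; with K=1 the fit is identical to the unmodified
    combined analysis.
    """
    from .association import select_reference  # local to avoid cycle at import

    if not cohort.trios:
        raise ValueError("M-HGLM requires trio data to anchor the combined fit")
    if cohort.n2 + cohort.n3 == 0:
        raise ValueError("M-HGLM requires unrelated case-control samples")
    gm = cohort.genotypes
    cc_rows = list(cohort.unrelated_case_idx) + list(cohort.unrelated_control_idx)
    cc = gm.subset(cc_rows)
    Z = normalize_genotypes(cc.geno)
    clusters = cluster_samples(Z, method=method, K=K, seed=seed)

    trio_hf = em_trios(gm, cohort.trios, tol=tol, max_iter=max_iter)
    cluster_hfs: list[HaplotypeFrequencySet] = []
    for k in range(1, K + 1):
        members = np.flatnonzero(clusters.labels == k)
        if len(members) < 2:
            raise ValueError(
                f"cluster {k} has {len(members)} sample(s); choose a smaller K"
            )
        sub = cc.subset(members)
        hf = em_unrelated(sub, tol=tol, max_iter=max_iter,
                          source_label=f"cluster-{k}")
        cluster_hfs.append(hf)

    space = union_space(trio_hf.haplotypes,
                        *[hf.haplotypes for hf in cluster_hfs])
    trio_hf_x = extend_to_space(trio_hf, space)
    case_m, pseudo_m = trio_weighted_count_matrices(gm, cohort.trios, trio_hf_x)
    cc_counts = np.zeros((cc.n_samples, len(space)))
    for k, hf in enumerate(cluster_hfs, start=1):
        members = np.flatnonzero(clusters.labels == k)
        hf_x = extend_to_space(hf, space)
        cc_counts[members] = weighted_count_matrix(cc.subset(members), hf_x)

    if reference is None:
        pooled = np.concatenate([case_m, pseudo_m, cc_counts]).mean(axis=0) / 2
        reference = select_reference(dict(zip(space, pooled)))
    design = design_from_matrices(case_m, pseudo_m, cc_counts,
                                  cc.phenotype.astype(float), space,
                                  reference, rare_threshold)
    n_trio_rows = case_m.shape[0] + pseudo_m.shape[0]
    if cluster_main_effects and K > 1:
        # indicator per cluster beyond the first; trio rows share the
        # baseline with cluster 1
        ind = np.zeros((design.N, K - 1))
        for k in range(2, K + 1):
            members = np.flatnonzero(clusters.labels == k)
            ind[n_trio_rows + members, k - 2] = 1.0
        design = CombinedDesign(
            y=design.y,
            H=np.hstack([design.H, ind]),
            column_haplotypes=design.column_haplotypes
            + [f"cluster-{k}" for k in range(2, K + 1)],
            reference=design.reference,
            source_group=design.source_group,
        )
    fit = fit_hglm(design, global_test=global_test)
    # the haplotype-level global test must not count the cluster columns:
    # compare against the reduced model keeping intercept + cluster terms
    if cluster_main_effects and K > 1:
        from scipy import stats as _st

        from .association import _fit_logit

        n_hap = len(fit.column_haplotypes) - (K - 1)
        if global_test == "lrt":
            Xr = np.column_stack([np.ones(design.N), ind])
            _, _, ll_red, ok_red, _ = _fit_logit(Xr, design.y)
            if np.isfinite(fit.loglik) and np.isfinite(ll_red):
                gstat = max(2.0 * (fit.loglik - ll_red), 0.0)
            else:
                gstat = np.nan
        else:
            sub_beta = fit.beta[:n_hap]
            sub_cov = fit.cov[1:n_hap + 1, 1:n_hap + 1]
            try:
                gstat = float(sub_beta @ np.linalg.solve(sub_cov, sub_beta))
            except np.linalg.LinAlgError:
                gstat = np.nan
        gp = float(_st.chi2.sf(gstat, n_hap)) if np.isfinite(gstat) else np.nan
        fit.global_stat, fit.global_df, fit.global_p = gstat, n_hap, gp
    return MHGLMResult(fit=fit, design=design, clusters=clusters,
                       cluster_hfs=cluster_hfs, trio_hf=trio_hf)
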