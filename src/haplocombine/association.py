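"""The haplotype generalized linear model (HGLM) and its comparators.

The HGLM is an ordinary logistic regression of affection status on
haplotype weighted-count covariates,

    logit P(y = 1 | H) = alpha + H' beta,

fitted on the stacked rows of all data sources (each trio contributes an
affected-child case row and a Falk-Rubenstein pseudo-control row; each
unrelated sample contributes one row).  Because every row's counts sum
to 2, the most common haplotype h0 is dropped from the design; exp(beta_k)
is then the haplotype odds ratio (HOR) of h_k relative to h0.

Weighted counts enter as fixed covariates — the phase-uncertainty of the
two-stage expectation-substitution approach is deliberately not propagated
into the standard errors.

For family-only data the matched-pair conditional logistic model (CLG) is
provided: the case/pseudo-control pair of a trio forms a matched set and
only the within-pair count difference is informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .datamodel import Haplotype
from .phasing import WeightedCountRow

__all__ = [
    "CombinedDesign",
    "HGLMFit",
    "CLGFit",
    "select_reference",
    "build_design",
    "design_from_matrices",
    "fit_hglm",
    "haplotype_ci",
    "fit_clg",
]

RARE_LABEL = "rare"
NUMERICAL_ZERO_FREQ = 1e-8


@dataclass
class CombinedDesign:
    """Stacked phenotype/covariate matrix with the reference column removed."""

    y: np.ndarray                      # binary, length N
    H: np.ndarray                      # N x p weighted counts
    column_haplotypes: list            # Haplotype or the string "rare"
    reference: Haplotype
    source_group: np.ndarray           # per-row: "trio" | "case-control"

    @property
    def N(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.H.shape[1]


@dataclass
class HGLMFit:
    alpha: float
    beta: np.ndarray
    cov: np.ndarray                    # (p+1) x (p+1), intercept first
    wald_z: np.ndarray
    wald_p: np.ndarray
    global_stat: float
    global_df: int
    global_p: float
    converged: bool
    n_iter: int
    column_haplotypes: list
    reference: Haplotype | None = None
    loglik: float = np.nan
    null_loglik: float = np.nan

    @property
    def hor(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov)[1:], 0.0, None))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "haplotype": [str(h) for h in self.column_haplotypes],
            "log_hor": self.beta,
            "se": self.se,
            "hor": self.hor,
            "wald_z": self.wald_z,
            "p_value": self.wald_p,
        })


@dataclass
class CLGFit:
    beta: np.ndarray
    cov: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    global_stat: float
    global_df: int
    global_p: float
    converged: bool
    n_iter: int
    column_haplotypes: list

    @property
    def hor(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def select_reference(pooled_freqs: Mapping[Haplotype, float]) -> Haplotype:
    """Most common haplotype; ties go to the smallest allele string."""
    if not pooled_freqs:
        raise ValueError("empty frequency table")
    best = max(pooled_freqs, key=lambda h: (pooled_freqs[h], [-a for a in h.alleles]))
    # the key above prefers higher frequency, then lexicographically
    # *smaller* allele vector (negated for max())
    return best


def _stack_rows(rows: Sequence[WeightedCountRow]) -> tuple[np.ndarray, np.ndarray]:
    if not rows:
        return np.zeros((0, 0)), np.zeros(0)
    space = rows[0].haplotypes
    for r in rows:
        if r.haplotypes != space:
            raise ValueError(
                "weighted-count rows use different haplotype index spaces; "
                "align them with union_space/extend_to_space first"
            )
    M = np.stack([r.counts for r in rows])
    y = np.array([r.phenotype for r in rows], dtype=float)
    return M, y


def design_from_matrices(
    trio_case: np.ndarray, trio_pseudo: np.ndarray,
    cc_counts: np.ndarray, cc_pheno: np.ndarray,
    haplotypes: list[Haplotype], reference: Haplotype,
    rare_threshold: float = 0.0,
) -> CombinedDesign:
    """Build the stacked design from per-source count matrices.

    Trio rows come first (all case rows, then all pseudo-control rows),
    then unrelated rows.  The reference column is removed; columns whose
    pooled frequency falls below ``rare_threshold`` are merged into one
    "rare" column; columns never observed are dropped.
    """
    if reference not in haplotypes:
        raise ValueError(f"reference haplotype {reference} not in index space")
    blocks = [b for b in (trio_case, trio_pseudo, cc_counts) if b.size]
    M = np.vstack(blocks) if blocks else np.zeros((0, len(haplotypes)))
    n_trio = trio_case.shape[0] + trio_pseudo.shape[0]
    y = np.concatenate([
        np.ones(trio_case.shape[0]),
        np.zeros(trio_pseudo.shape[0]),
        np.asarray(cc_pheno, dtype=float),
    ])
    source = np.array(["trio"] * n_trio + ["case-control"] * len(cc_pheno))

    pooled = M.mean(axis=0) / 2.0 if len(M) else np.zeros(len(haplotypes))
    ref_idx = haplotypes.index(reference)
    keep, rare = [], []
    for j in range(len(haplotypes)):
        if j == ref_idx:
            continue
        if pooled[j] <= NUMERICAL_ZERO_FREQ:
            # EM support can carry haplotypes at numerically-zero mass;
            # their all-zero columns would only degrade the Hessian
            continue
        if pooled[j] < rare_threshold:
            rare.append(j)
        else:
            keep.append(j)
    cols = [haplotypes[j] for j in keep]
    X = M[:, keep]
    if rare:
        X = np.hstack([X, M[:, rare].sum(axis=1, keepdims=True)])
        cols = cols + [RARE_LABEL]
    return CombinedDesign(y=y, H=X, column_haplotypes=cols,
                          reference=reference, source_group=source)


def build_design(trio_rows: Sequence[WeightedCountRow],
                 cc_rows: Sequence[WeightedCountRow],
                 reference: Haplotype,
                 rare_threshold: float = 0.0) -> CombinedDesign:
    """Stack weighted-count rows into a fit-ready design (trios first)."""
    case_rows = [r for r in trio_rows if r.phenotype == 1]
    pseudo_rows = [r for r in trio_rows if r.phenotype == 0]
    space = None
    for r in list(trio_rows) + list(cc_rows):
        if space is None:
            space = r.haplotypes
        elif r.haplotypes != space:
            raise ValueError("rows use inconsistent haplotype index spaces")
    if space is None:
        raise ValueError("no rows supplied")
    tc, _ = _stack_rows(case_rows)
    tp, _ = _stack_rows(pseudo_rows)
    cc, ccy = _stack_rows(list(cc_rows))
    if not len(case_rows):
        tc = np.zeros((0, len(space)))
    if not len(pseudo_rows):
        tp = np.zeros((0, len(space)))
    if not len(cc_rows):
        cc = np.zeros((0, len(space)))
        ccy = np.zeros(0)
    return design_from_matrices(tc, tp, cc, ccy, list(space), reference,
                                rare_threshold)


def _fit_logit(X: np.ndarray, y: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Logistic MLE via statsmodels Newton-Raphson (IRLS).

    Returns (params, covariance, loglik, converged, iterations); a
    separation failure yields NaN parameters and converged=False rather
    than an exception, so replicate harnesses can count and skip it.
    """
    k = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", disp=0, maxiter=100)
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        ok = bool(res.mle_retvals.get("converged", False))
        n_iter = int(res.mle_retvals.get("iterations", 0))
        llf = float(res.llf)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return np.full(k, np.nan), np.full((k, k), np.nan), np.nan, False, 0
    if not np.isfinite(params).all() or np.abs(params).max() > 30:
        ok = False  # quasi-complete separation: estimates diverging
    if not np.isfinite(cov).all() or np.diag(cov).min() < -1e-8:
        ok = False  # singular/indefinite observed information
    return params, cov, llf, ok, n_iter


def fit_hglm(design: CombinedDesign, global_test: str = "lrt") -> HGLMFit:
    """Maximum-likelihood logistic fit of the HGLM.

    The haplotype-specific test is the two-sided Wald test of beta_k = 0;
    the global test is by default the likelihood-ratio chi-square against
    the intercept-only model on ``p`` degrees of freedom (``global_test=
    "wald"`` uses the multivariate Wald statistic instead).
    """
    y, H = design.y, design.H
    if len(np.unique(y)) < 2:
        raise ValueError("both phenotype classes must be present")
    if H.shape[1] == 0:
        raise ValueError("design has no haplotype columns")
    X = np.column_stack([np.ones(len(y)), H])
    params, cov, llf, ok, n_iter = _fit_logit(X, y)
    p = H.shape[1]
    ybar = y.mean()
    ll0 = float(len(y) * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar)))
    beta = params[1:]
    se = np.sqrt(np.maximum(np.diag(cov)[1:], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    if global_test == "lrt":
        gstat = max(2.0 * (llf - ll0), 0.0) if np.isfinite(llf) else np.nan
    elif global_test == "wald":
        try:
            vb = cov[1:, 1:]
            gstat = float(beta @ np.linalg.solve(vb, beta))
        except np.linalg.LinAlgError:
            gstat = np.nan
    else:
        raise ValueError(f"unknown global_test {global_test!r}")
    gp = float(stats.chi2.sf(gstat, p)) if np.isfinite(gstat) else np.nan
    return HGLMFit(
        alpha=float(params[0]), beta=beta, cov=cov, wald_z=z, wald_p=wald_p,
        global_stat=float(gstat), global_df=p, global_p=gp,
        converged=bool(ok and np.isfinite(se).all()), n_iter=n_iter,
        column_haplotypes=list(design.column_haplotypes),
        reference=design.reference, loglik=llf, null_loglik=ll0,
    )


def haplotype_ci(fit: HGLMFit, level: float = 0.95) -> pd.DataFrame:
    """Wald confidence intervals for the haplotype odds ratios."""
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    zq = stats.norm.ppf(1.0 - (1.0 - level) / 2.0) if level > 0 else 0.0
    lo = np.exp(fit.beta - zq * fit.se)
    hi = np.exp(fit.beta + zq * fit.se)
    return pd.DataFrame({
        "haplotype": [str(h) for h in fit.column_haplotypes],
        "hor": fit.hor, "lower": lo, "upper": hi,
    })


def fit_clg(pairs: Sequence[tuple[WeightedCountRow, WeightedCountRow]],
            reference: Haplotype | None = None) -> CLGFit:
    """Matched-pair conditional logistic fit on trio case/pseudo-control pairs.

    The conditional likelihood of each 1:1 matched set reduces to a
    no-intercept logistic model on the within-pair count difference
    d_i = (case counts) - (pseudo-control counts), with the reference
    column dropped.
    """
    if not pairs:
        raise ValueError("at least one matched pair is required")
    space = pairs[0][0].haplotypes
    D = np.stack([case.counts - pseudo.counts for case, pseudo in pairs])
    cols = list(space)
    if reference is not None:
        if reference not in cols:
            raise ValueError(f"reference {reference} not in index space")
        j = cols.index(reference)
        D = np.delete(D, j, axis=1)
        cols = [h for h in cols if h != reference]
    # drop columns with no within-pair variation (uninformative)
    informative = np.abs(D).sum(axis=0) > 0
    if not informative.any():
        raise ValueError("all within-pair differences are zero: "
                         "no conditional information")
    D = D[:, informative]
    cols = [h for h, keep in zip(cols, informative) if keep]
    n, p = D.shape
    y1 = np.ones(n)
    beta, cov, llf, ok, n_iter = _fit_logit(D, y1)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    ll0 = -n * np.log(2.0)
    gstat = max(2.0 * (llf - ll0), 0.0) if np.isfinite(llf) else np.nan
    return CLGFit(
        beta=beta, cov=cov, wald_z=z, wald_p=wald_p,
        global_stat=float(gstat), global_df=p,
        global_p=float(stats.chi2.sf(gstat, p)),
        converged=bool(ok), n_iter=n_iter, column_haplotypes=cols,
    )
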