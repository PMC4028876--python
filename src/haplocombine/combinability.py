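"""ANOVA/MANOVA tests of whether trio and case-control data may be pooled.

The mean weighted-count vector of a source, divided by two, estimates
that source's haplotype frequency vector.  Comparing the source-wise
means therefore tests the equality of haplotype frequencies between the
trio-derived rows and the unrelated case-control rows: a rejection
signals population stratification (or genuine effect heterogeneity) and
warns against pooling the two sources directly.  The two mechanisms are
not distinguishable from these data; the test is a combined
"do-not-combine" indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CombinabilityResult", "manova_combinability", "anova_per_haplotype"]


@dataclass
class CombinabilityResult:
    manova_stat: float          # Pillai's trace (or Wilks' lambda)
    manova_F: float
    manova_df1: float
    manova_df2: float
    manova_p: float
    statistic: str
    per_haplotype: pd.DataFrame  # columns: column, F, df1, df2, p
    group_means: pd.DataFrame    # one row per source group
    alpha: float
    combine_ok: bool


def _one_way_groups(H: np.ndarray, group: np.ndarray
                    ) -> tuple[np.ndarray, list, list[np.ndarray]]:
    H = np.asarray(H, dtype=float)
    if H.ndim == 1:
        H = H[:, None]
    group = np.asarray(group)
    labels = sorted(pd.unique(group).tolist(), key=str)
    if len(labels) != 2:
        raise ValueError("exactly two source groups are required")
    parts = [H[group == g] for g in labels]
    if any(len(p) == 0 for p in parts):
        raise ValueError("both groups must be non-empty")
    return H, labels, parts


def manova_combinability(H: np.ndarray, group: np.ndarray,
                         alpha: float = 0.05,
                         statistic: str = "pillai") -> CombinabilityResult:
    """One-way MANOVA of weighted-count rows on data source.

    With two groups every classical MANOVA statistic reduces to a
    function of Hotelling's T^2 and the F approximation is exact:
    F = (N - p - 1)/p * V/(1 - V) on (p, N - p - 1) df for Pillai's V.
    """
    H, labels, parts = _one_way_groups(H, group)
    N, p = H.shape
    if N <= p + 2:
        raise ValueError("too few rows for a p-dimensional MANOVA")
    grand = H.mean(axis=0)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for part in parts:
        m = part.mean(axis=0)
        d = (m - grand)[:, None]
        B += len(part) * (d @ d.T)
        C = part - m
        W += C.T @ C
    try:
        WB = np.linalg.solve(W, B)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular within-group covariance; consider pooling rare "
            "haplotypes (rare_threshold) before testing"
        ) from err
    # two groups: rank(B) = 1, single non-zero eigenvalue
    lam = float(np.trace(WB))
    df1, df2 = p, N - p - 1
    if statistic == "pillai":
        stat = lam / (1.0 + lam)
    elif statistic == "wilks":
        stat = 1.0 / (1.0 + lam)
    else:
        raise ValueError("statistic must be 'pillai' or 'wilks'")
    F = (df2 / df1) * lam
    pval = float(stats.f.sf(F, df1, df2))

    per_h = anova_table(H, group)
    means = pd.DataFrame([part.mean(axis=0) for part in parts],
                         index=[str(g) for g in labels])
    return CombinabilityResult(
        manova_stat=float(stat), manova_F=float(F), manova_df1=df1,
        manova_df2=df2, manova_p=pval, statistic=statistic,
        per_haplotype=per_h, group_means=means, alpha=alpha,
        combine_ok=bool(pval >= alpha),
    )


def anova_table(H: np.ndarray, group: np.ndarray) -> pd.DataFrame:
    """Column-wise one-way ANOVA F tests of source-mean equality."""
    H, labels, parts = _one_way_groups(H, group)
    N, p = H.shape
    rows = []
    for j in range(p):
        cols = [part[:, j] for part in parts]
        if all(np.ptp(c) == 0 for c in cols) and np.ptp(H[:, j]) == 0:
            warnings.warn(f"column {j} has zero variance; ANOVA p set to 1")
            rows.append((j, 0.0, 1.0, float(N - 2), 1.0))
            continue
        F, pval = stats.f_oneway(*cols)
        rows.append((j, float(F), 1.0, float(N - 2), float(pval)))
    return pd.DataFrame(rows, columns=["column", "F", "df1", "df2", "p"])


def anova_per_haplotype(H: np.ndarray, group: np.ndarray,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-haplotype source-mean comparison with a reject flag."""
    tab = anova_table(H, group)
    tab["reject"] = tab["p"] < alpha
    return tab
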