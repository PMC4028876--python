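"""Replicate harness: FPR, power, bias, MSE and CI coverage over simulations.

Runs any of the analyses (population-only / family-only / combined HGLM,
the matched-pair CLG, cluster-corrected M-HGLM, and the ANOVA/MANOVA
combinability tests) over simulated replicates of a scenario and
aggregates the classical operating characteristics: the fraction of
replicates with p < alpha is the empirical FPR when the true haplotype
odds ratio is 1 and the empirical power otherwise; bias and MSE are on
the odds-ratio scale by default.  Replicates whose fit fails to converge
(e.g. through quasi-complete separation) are excluded from denominators
and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (
    design_from_matrices,
    fit_clg,
    fit_hglm,
    haplotype_ci,
)
from .combinability import manova_combinability
from .phasing import (
    WeightedCountRow,
    em_trios,
    em_unrelated,
    extend_to_space,
    trio_weighted_count_matrices,
    union_space,
    weighted_count_matrix,
)
from .simulate import SimulationScenario, simulate_cohort
from .stratification import fit_mhglm

__all__ = ["EvaluationSummary", "run_replicates", "run_replicates_multi",
           "summarize_bias_mse", "reproduce_table", "METHODS", "TABLE_IDS"]

METHODS = ("p-hglm", "f-hglm", "f-clg", "c-hglm",
           "m-hglm-kmeans", "m-hglm-ward", "anova")
TABLE_IDS = ("T1", "T2", "T3", "T4", "T5", "T6")


@dataclass
class EvaluationSummary:
    scenario: str
    method: str
    reps_requested: int
    reps_converged: int
    alpha: float
    per_haplotype: pd.DataFrame   # haplotype, true_hor, rejection_rate, ...
    overall_rejection: float
    records: pd.DataFrame         # per-replicate raw results

    @property
    def mc_se(self) -> pd.Series:
        """Monte-Carlo standard error of each rejection rate."""
        r = self.per_haplotype["rejection_rate"]
        n = max(self.reps_converged, 1)
        return np.sqrt(r * (1 - r) / n)


def summarize_bias_mse(estimates: np.ndarray, truth: np.ndarray,
                       log_scale: bool = False) -> pd.DataFrame:
    """Per-haplotype bias and MSE of odds-ratio estimates.

    ``estimates`` is (replicates x haplotypes) on the HOR scale; with
    ``log_scale`` both estimates and truth are log-transformed first.
    """
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    truth = np.asarray(truth, dtype=float)
    if estimates.shape[0] == 0:
        raise ValueError("no estimates supplied")
    if log_scale:
        estimates = np.log(estimates)
        truth = np.log(truth)
    err = estimates - truth
    return pd.DataFrame({
        "bias": np.nanmean(err, axis=0),
        "mse": np.nanmean(err ** 2, axis=0),
    })


def _replicate_analyses(ds, methods: list[str], alpha: float,
                        seed: int, mhglm_K: int, ci_level: float) -> dict:
    """All requested analyses of one simulated dataset."""
    cohort = ds.cohort
    scenario: SimulationScenario = ds.scenario
    gm = cohort.genotypes
    ref = scenario.reference
    report_haps = [h for h in scenario.haplotypes if h != ref]
    out: dict[str, dict] = {}

    need_trio = bool(set(methods) & {"f-hglm", "f-clg", "c-hglm", "anova",
                                     "m-hglm-kmeans", "m-hglm-ward"})
    need_cc = bool(set(methods) & {"p-hglm", "c-hglm", "anova",
                                   "m-hglm-kmeans", "m-hglm-ward"})
    tc = tp = ccm = None
    spaces = []
    thf = uhf = None
    if need_trio and cohort.trios:
        thf = em_trios(gm, cohort.trios)
        spaces.append(thf.haplotypes)
    cc = None
    if need_cc and (cohort.n2 + cohort.n3):
        cc = gm.subset(list(cohort.unrelated_case_idx)
                       + list(cohort.unrelated_control_idx))
        uhf = em_unrelated(cc)
        spaces.append(uhf.haplotypes)
    space = union_space(*spaces) if spaces else []
    if thf is not None:
        tc, tp = trio_weighted_count_matrices(
            gm, cohort.trios, extend_to_space(thf, space))
    if uhf is not None:
        ccm = weighted_count_matrix(cc, extend_to_space(uhf, space))

    empty = np.zeros((0, len(space)))

    def record_fit(fit, label):
        rec = {"converged": bool(fit.converged),
               "overall_p": float(fit.global_p) if fit.converged else np.nan}
        names = [str(h) for h in fit.column_haplotypes]
        ci = None
        if hasattr(fit, "alpha") and fit.converged:
            ci = haplotype_ci(fit, ci_level)
        for h in report_haps:
            hs = str(h)
            if fit.converged and hs in names:
                j = names.index(hs)
                rec[f"p:{hs}"] = float(fit.wald_p[j])
                rec[f"hor:{hs}"] = float(np.exp(fit.beta[j]))
                if ci is not None:
                    rec[f"lo:{hs}"] = float(ci["lower"].iloc[j])
                    rec[f"hi:{hs}"] = float(ci["upper"].iloc[j])
            else:
                rec[f"p:{hs}"] = np.nan
                rec[f"hor:{hs}"] = np.nan
        out[label] = rec

    for m in methods:
        if m == "p-hglm":
            d = design_from_matrices(empty, empty, ccm,
                                     cc.phenotype.astype(float), space, ref)
            record_fit(fit_hglm(d), m)
        elif m == "f-hglm":
            d = design_from_matrices(tc, tp, empty, np.zeros(0), space, ref)
            record_fit(fit_hglm(d), m)
        elif m == "f-clg":
            pairs = [
                (WeightedCountRow(tc[i], space, "trio-case", 1),
                 WeightedCountRow(tp[i], space, "trio-pseudocontrol", 0))
                for i in range(tc.shape[0])
            ]
            record_fit(fit_clg(pairs, reference=ref), m)
        elif m == "c-hglm":
            d = design_from_matrices(tc, tp, ccm,
                                     cc.phenotype.astype(float), space, ref)
            record_fit(fit_hglm(d), m)
        elif m in ("m-hglm-kmeans", "m-hglm-ward"):
            res = fit_mhglm(cohort, method=m.split("-")[-1], K=mhglm_K,
                            seed=seed, reference=ref)
            record_fit(res.fit, m)
        elif m == "anova":
            H = np.vstack([tc, tp, ccm])
            grp = np.array(["trio"] * (len(tc) + len(tp))
                           + ["case-control"] * len(ccm))
            ref_j = space.index(ref)
            Hn = np.delete(H, ref_j, axis=1)
            cols = [h for h in space if h != ref]
            # drop all-zero columns (haplotypes unobserved in this replicate)
            nz = Hn.sum(axis=0) > 1e-8
            mv = manova_combinability(Hn[:, nz], grp, alpha=alpha)
            names = [str(h) for h, keep in zip(cols, nz) if keep]
            rec = {"converged": True, "overall_p": float(mv.manova_p)}
            for h in report_haps:
                hs = str(h)
                if hs in names:
                    rec[f"p:{hs}"] = float(
                        mv.per_haplotype["p"].iloc[names.index(hs)])
                else:
                    rec[f"p:{hs}"] = np.nan
                rec[f"hor:{hs}"] = np.nan
            out[m] = rec
        else:
            raise ValueError(f"unknown method {m!r}; known: {METHODS}")
    return out


def run_replicates_multi(scenario: SimulationScenario, methods: list[str],
                         reps: int, base_seed: int, alpha: float = 0.05,
                         mhglm_K: int = 2, ci_level: float = 0.95,
                         ) -> dict[str, EvaluationSummary]:
    """Run several analyses on the same stream of simulated replicates."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; known: {METHODS}")
    rows: dict[str, list[dict]] = {m: [] for m in methods}
    for r in range(reps):
        seed = base_seed + r
        ds = simulate_cohort(scenario, seed=seed)
        recs = _replicate_analyses(ds, methods, alpha, seed, mhglm_K, ci_level)
        for m in methods:
            recs[m]["replicate"] = r
            rows[m].append(recs[m])
    ref = scenario.reference
    report_haps = [h for h in scenario.haplotypes if h != ref]
    out = {}
    for m in methods:
        records = pd.DataFrame(rows[m])
        conv = records[records["converged"]]
        per = []
        for h in report_haps:
            hs = str(h)
            pvals = conv[f"p:{hs}"].to_numpy()
            entry = {
                "haplotype": hs,
                "true_hor": scenario.hor_of(h),
                "rejection_rate": float(np.nanmean(pvals < alpha))
                if len(conv) else np.nan,
            }
            if f"hor:{hs}" in conv and conv[f"hor:{hs}"].notna().any():
                est = conv[f"hor:{hs}"].to_numpy()
                bm = summarize_bias_mse(est[:, None],
                                        np.array([scenario.hor_of(h)]))
                entry["bias"] = float(bm["bias"].iloc[0])
                entry["mse"] = float(bm["mse"].iloc[0])
                if f"lo:{hs}" in conv:
                    cover = ((conv[f"lo:{hs}"] <= scenario.hor_of(h))
                             & (scenario.hor_of(h) <= conv[f"hi:{hs}"]))
                    entry["ci_coverage"] = float(cover.mean())
            per.append(entry)
        out[m] = EvaluationSummary(
            scenario=scenario.name, method=m, reps_requested=reps,
            reps_converged=int(records["converged"].sum()), alpha=alpha,
            per_haplotype=pd.DataFrame(per),
            overall_rejection=float((conv["overall_p"] < alpha).mean())
            if len(conv) else np.nan,
            records=records,
        )
    return out


def run_replicates(scenario: SimulationScenario, method: str, reps: int,
                   base_seed: int, alpha: float = 0.05, mhglm_K: int = 2,
                   ci_level: float = 0.95) -> EvaluationSummary:
    """Operating characteristics of one analysis over simulated replicates."""
    return run_replicates_multi(scenario, [method], reps, base_seed,
                                alpha=alpha, mhglm_K=mhglm_K,
                                ci_level=ci_level)[method]


# ---------------------------------------------------------------------------
# table reproduction

def _table_cells(table_id: str):
    from .simulate import preset_scenario

    sizes = [(100, 100, 100), (500, 1000, 1000)]
    if table_id == "T1":
        return [(preset_scenario("null2", *s),
                 ["p-hglm", "f-hglm", "f-clg", "c-hglm"]) for s in sizes]
    if table_id == "T2":
        return [(preset_scenario(name, *s),
                 ["p-hglm", "f-hglm", "f-clg", "c-hglm"])
                for name in ("mild2", "moderate2") for s in sizes]
    if table_id == "T3":
        return [(preset_scenario("snp5", *s),
                 ["p-hglm", "f-hglm", "f-clg", "c-hglm"]) for s in sizes]
    if table_id == "T4":
        return [(preset_scenario(name, *s), ["anova"])
                for name in ("ps1", "ps2") for s in sizes]
    if table_id == "T5":
        return [(preset_scenario(name, 100, 100, 100),
                 ["f-hglm", "c-hglm", "m-hglm-kmeans", "m-hglm-ward"])
                for name in ("ps1", "ps2")]
    if table_id == "T6":
        return [(preset_scenario(name, 500, 1000, 1000),
                 ["f-hglm", "c-hglm", "m-hglm-kmeans", "m-hglm-ward"])
                for name in ("ps1", "ps2")]
    raise ValueError(f"unknown table id {table_id!r}; known: {TABLE_IDS}")


def reproduce_table(table_id: str, reps: int = 1000, base_seed: int = 0,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Re-run every scenario x method cell of one summary table.

    Returns a long-format frame: scenario, sample sizes, method,
    haplotype ("overall" for the global test), true HOR, rejection rate
    with its Monte-Carlo SE, bias/MSE/coverage where defined, and the
    count of converged replicates.
    """
    frames = []
    for scenario, methods in _table_cells(table_id):
        summaries = run_replicates_multi(scenario, methods, reps, base_seed,
                                         alpha=alpha)
        for m, s in summaries.items():
            base = {
                "table": table_id, "scenario": scenario.name,
                "n1": scenario.n1, "n2": scenario.n2, "n3": scenario.n3,
                "method": m, "reps": reps, "converged": s.reps_converged,
            }
            r = s.overall_rejection
            frames.append({**base, "haplotype": "overall", "true_hor": np.nan,
                           "rejection_rate": r,
                           "mc_se": np.sqrt(r * (1 - r)
                                            / max(s.reps_converged, 1))})
            for _, row in s.per_haplotype.iterrows():
                rr = row["rejection_rate"]
                frames.append({
                    **base, "haplotype": row["haplotype"],
                    "true_hor": row["true_hor"], "rejection_rate": rr,
                    "mc_se": np.sqrt(rr * (1 - rr)
                                     / max(s.reps_converged, 1)),
                    "bias": row.get("bias", np.nan),
                    "mse": row.get("mse", np.nan),
                    "ci_coverage": row.get("ci_coverage", np.nan),
                })
    return pd.DataFrame(frames)
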