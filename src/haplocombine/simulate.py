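"""Scenario-based synthetic genotype generation.

The generator reproduces the study conditions of the simulation designs
the package is validated against:

* 2-SNP haplotype pools (frequencies 0.5/0.1/0.3/0.1 over 1-1, 1-2, 2-1,
  2-2) with null, mild and moderate haplotype odds ratios;
* a 5-SNP, six-haplotype pool with one strong-risk haplotype;
* two admixed-population stratification scenarios in which two
  subpopulations differ in both haplotype frequencies and disease
  prevalence while no haplotype is associated within either
  subpopulation.

Case-control data follow a two-step pool mechanism: a large pool of
haplotype sequences is paired into individuals, affection is assigned by
a logistic model on haplotype dosages (intercept calibrated to a target
prevalence of 6%), the haplotypes are split into case and control pools
by their carrier's status, and each output case (control) re-draws two
haplotypes from the case (control) pool.  Trios are ascertained on an
affected child: the child's diplotype is generated first from the case
diplotype distribution under the same logistic model, and each parent is
completed with an untransmitted haplotype drawn from the population
frequencies (random mating).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .datamodel import CohortData, GenotypeMatrix, Haplotype, TrioRecord, PHENO_UNKNOWN

__all__ = [
    "PSSpec",
    "SimulationScenario",
    "SimulatedDataset",
    "preset_scenario",
    "calibrate_intercept",
    "simulate_case_control",
    "simulate_trios",
    "simulate_admixed",
    "simulate_cohort",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("null2", "mild2", "moderate2", "snp5", "ps1", "ps2")


@dataclass(frozen=True)
class PSSpec:
    """Two-subpopulation admixture with prevalence heterogeneity."""

    freqs_a: tuple[float, ...]
    prev_a: float
    freqs_b: tuple[float, ...]
    prev_b: float
    mix: tuple[float, float] = (0.5, 0.5)     # (weight A, weight B)
    trio_source: str = "subpopB"              # "subpopB" | "admixed"

    def __post_init__(self) -> None:
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if self.trio_source not in ("subpopB", "admixed"):
            raise ValueError(f"unknown trio_source {self.trio_source!r}")


@dataclass
class SimulationScenario:
    name: str
    haplotypes: list[Haplotype]
    freqs: np.ndarray
    hor: np.ndarray                 # odds ratio per haplotype (reference = 1)
    reference: Haplotype
    target_prevalence: float = 0.06
    pool_size: int = 20_000
    n1: int = 100
    n2: int = 100
    n3: int = 100
    ps: PSSpec | None = None
    alpha: float | None = None      # calibrated lazily

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.hor = np.asarray(self.hor, dtype=float)
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if self.reference not in self.haplotypes:
            raise ValueError("reference haplotype not in pool")

    @property
    def q(self) -> int:
        return self.haplotypes[0].q

    @property
    def beta(self) -> np.ndarray:
        """Log odds ratios aligned with ``haplotypes`` (reference = 0)."""
        return np.log(self.hor)

    def hor_of(self, h: Haplotype) -> float:
        return float(self.hor[self.haplotypes.index(h)])


@dataclass
class SimulatedDataset:
    """A cohort plus the generating truth (diplotypes, subpopulations)."""

    cohort: CohortData
    scenario: SimulationScenario
    true_diplotypes: np.ndarray      # (n_samples, 2) haplotype indices, -1 n/a
    subpopulation: np.ndarray        # per-sample 0 (A) / 1 (B) / -1 n/a


# ---------------------------------------------------------------------------

_PRESET_2SNP_HAPS = ["1-1", "1-2", "2-1", "2-2"]
_PRESET_2SNP_FREQS = (0.5, 0.1, 0.3, 0.1)
_PRESET_5SNP = [
    ("1-2-1-2-2", 0.264, 1.0),       # reference
    ("1-1-1-1-1", 0.169, 1.467),
    ("1-1-2-1-1", 0.067, 3.811),
    ("1-2-2-2-2", 0.050, 1.528),
    ("2-2-2-2-1", 0.212, 1.309),
    ("2-2-2-2-2", 0.237, 1.501),
]


def preset_scenario(name: str, n1: int = 100, n2: int = 100, n3: int = 100,
                    mix: tuple[float, float] = (0.5, 0.5),
                    ) -> SimulationScenario:
    """Named study conditions; see the module docstring for the catalogue."""
    haps2 = [Haplotype.from_string(s) for s in _PRESET_2SNP_HAPS]
    if name == "null2":
        hor = (1.0, 1.0, 1.0, 1.0)
    elif name == "mild2":
        hor = (1.0, 1.207, 1.421, 1.525)
    elif name == "moderate2":
        hor = (1.0, 1.0, 2.067, 2.067)
    elif name == "snp5":
        haps = [Haplotype.from_string(s) for s, _, _ in _PRESET_5SNP]
        freqs = np.array([f for _, f, _ in _PRESET_5SNP])
        freqs = freqs / freqs.sum()   # printed values sum to 0.999
        return SimulationScenario(
            name=name, haplotypes=haps, freqs=freqs,
            hor=np.array([h for _, _, h in _PRESET_5SNP]),
            reference=haps[0], pool_size=100_000, n1=n1, n2=n2, n3=n3,
        )
    elif name in ("ps1", "ps2"):
        ps = PSSpec(
            freqs_a=(0.5, 0.1, 0.3, 0.1), prev_a=0.07,
            freqs_b=(0.4, 0.3, 0.15, 0.15), prev_b=0.18,
            mix=mix, trio_source="subpopB" if name == "ps1" else "admixed",
        )
        return SimulationScenario(
            name=name, haplotypes=haps2, freqs=np.array(_PRESET_2SNP_FREQS),
            hor=np.ones(4), reference=haps2[0], n1=n1, n2=n2, n3=n3, ps=ps,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")
    return SimulationScenario(
        name=name, haplotypes=haps2, freqs=np.array(_PRESET_2SNP_FREQS),
        hor=np.array(hor), reference=haps2[0], n1=n1, n2=n2, n3=n3,
    )


def calibrate_intercept(scenario: SimulationScenario) -> float:
    """Intercept putting the HWE-averaged disease rate at the target.

    Solves sum_d P_HWE(d) expit(alpha + x(d)'beta) = target by bisection
    (the left side is strictly increasing in alpha).
    """
    b = scenario.beta
    pair_p = np.outer(scenario.freqs, scenario.freqs)
    pair_x = b[:, None] + b[None, :]

    def prevalence(alpha: float) -> float:
        return float((pair_p * expit(alpha + pair_x)).sum())

    target = scenario.target_prevalence
    alpha = brentq(lambda a: prevalence(a) - target, -40.0, 20.0,
                   xtol=1e-12)
    return float(alpha)


def _ensure_alpha(scenario: SimulationScenario) -> SimulationScenario:
    if scenario.alpha is None:
        scenario.alpha = calibrate_intercept(scenario)
    return scenario


def _geno_from_diplotypes(dipl: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """Genotype rows (allele-2 counts) from (n, 2) haplotype indices."""
    return dosage[dipl[:, 0]] + dosage[dipl[:, 1]]


def _dosage_matrix(haplotypes: list[Haplotype]) -> np.ndarray:
    return np.array([h.dosage for h in haplotypes], dtype=np.int8)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_status_pools(scenario: SimulationScenario, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Case and control haplotype pools from the logistic disease model."""
    K = len(scenario.haplotypes)
    pool = rng.choice(K, size=scenario.pool_size, p=scenario.freqs)
    pairs = pool.reshape(-1, 2)
    lp = scenario.alpha + scenario.beta[pairs].sum(axis=1)
    affected = rng.random(len(pairs)) < expit(lp)
    case_pool = pairs[affected].ravel()
    control_pool = pairs[~affected].ravel()
    if len(case_pool) < 2 or len(control_pool) < 2:
        raise RuntimeError("disease-status pool too small; enlarge pool_size")
    return case_pool, control_pool


def simulate_case_control(scenario: SimulationScenario, n_cases: int,
                          n_controls: int, seed=None) -> SimulatedDataset:
    """Unrelated cases and controls via the two-step pool mechanism."""
    scenario = _ensure_alpha(scenario)
    rng = _as_rng(seed)
    case_pool, control_pool = _draw_status_pools(scenario, rng)
    dip_cases = rng.choice(case_pool, size=(n_cases, 2))
    dip_controls = rng.choice(control_pool, size=(n_controls, 2))
    dipl = np.vstack([dip_cases, dip_controls])
    dosage = _dosage_matrix(scenario.haplotypes)
    geno = _geno_from_diplotypes(dipl, dosage)
    pheno = np.concatenate([np.ones(n_cases, dtype=np.int8),
                            np.zeros(n_controls, dtype=np.int8)])
    ids = [f"case{i + 1}" for i in range(n_cases)] + \
          [f"ctrl{i + 1}" for i in range(n_controls)]
    gm = GenotypeMatrix(ids, geno, pheno,
                        [f"snp{j + 1}" for j in range(scenario.q)])
    cohort = CohortData(
        genotypes=gm,
        unrelated_case_idx=list(range(n_cases)),
        unrelated_control_idx=list(range(n_cases, n_cases + n_controls)),
    )
    return SimulatedDataset(cohort, scenario, dipl,
                            np.full(len(dipl), -1, dtype=np.int8))


def _make_trios(alpha: float, beta: np.ndarray, freqs: np.ndarray, n1: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Parental haplotypes (n1, 4: f1 f2 m1 m2) and transmitted flags.

    Affected-child-first construction: the child's diplotype is drawn
    from the case diplotype distribution, proportional to
    f(h1) f(h2) expit(alpha + beta_h1 + beta_h2), and each parent is
    completed with one untransmitted haplotype drawn from the population
    frequencies (random mating).  The transmitted pair is always
    (f1, m1); f2/m2 are the untransmitted haplotypes.
    """
    K = len(freqs)
    pair_p = (np.outer(freqs, freqs)
              * expit(alpha + beta[:, None] + beta[None, :])).ravel()
    pair_p = pair_p / pair_p.sum()
    idx = rng.choice(K * K, size=n1, p=pair_p)
    untrans = rng.choice(K, size=(n1, 2), p=freqs)
    par = np.column_stack([idx // K, untrans[:, 0], idx % K, untrans[:, 1]])
    return par, np.ones(n1, dtype=bool)


def _trio_cohort(scenario: SimulationScenario, par: np.ndarray,
                 takes_A: np.ndarray, subpop: np.ndarray | None = None,
                 ) -> SimulatedDataset:
    n1 = par.shape[0]
    dosage = _dosage_matrix(scenario.haplotypes)
    f_dip = par[:, [0, 1]]
    m_dip = par[:, [2, 3]]
    c_dip = np.where(takes_A[:, None], par[:, [0, 2]], par[:, [1, 3]])
    genos, ids, phenos, dipl = [], [], [], []
    trios = []
    for i in range(n1):
        base = 3 * i
        trios.append(TrioRecord(base, base + 1, base + 2))
        for dip, tag, ph in ((f_dip[i], "f", PHENO_UNKNOWN),
                             (m_dip[i], "m", PHENO_UNKNOWN),
                             (c_dip[i], "c", 1)):
            genos.append(dosage[dip[0]] + dosage[dip[1]])
            ids.append(f"t{i + 1}{tag}")
            phenos.append(ph)
            dipl.append(dip)
    gm = GenotypeMatrix(ids, np.array(genos), np.array(phenos),
                        [f"snp{j + 1}" for j in range(scenario.q)])
    cohort = CohortData(genotypes=gm, trios=trios)
    sp = np.full(len(ids), -1, dtype=np.int8)
    if subpop is not None:
        sp = np.repeat(subpop, 3).astype(np.int8)
    return SimulatedDataset(cohort, scenario, np.array(dipl), sp)


def simulate_trios(scenario: SimulationScenario, n1: int,
                   seed=None) -> SimulatedDataset:
    """Case-parent trios ascertained on an affected child.

    The child's diplotype is generated first from the case distribution
    under the logistic disease model; the parents are completed under
    random mating.  Under the null every candidate pair is equally
    likely and transmission is symmetric.
    """
    scenario = _ensure_alpha(scenario)
    rng = _as_rng(seed)
    par, takes_A = _make_trios(scenario.alpha, scenario.beta,
                               scenario.freqs, n1, rng)
    return _trio_cohort(scenario, par, takes_A)


def simulate_admixed(scenario: SimulationScenario, seed=None,
                     ) -> SimulatedDataset:
    """Full cohort under an admixed-population stratification scenario.

    Within each subpopulation no haplotype is associated with disease
    (all odds ratios 1); affection is Bernoulli at the subpopulation's
    prevalence.  Cases and controls are sampled from a large admixed
    population of individuals, so the unrelated sample over-represents
    the higher-prevalence subpopulation among its cases.
    """
    ps = scenario.ps
    if ps is None:
        raise ValueError("scenario has no population-stratification block")
    rng = _as_rng(seed)
    K = len(scenario.haplotypes)
    n_pool = scenario.pool_size // 2
    sub = (rng.random(n_pool) < ps.mix[1]).astype(np.int8)  # 1 = subpop B
    freqs = np.vstack([ps.freqs_a, ps.freqs_b])
    prevs = np.array([ps.prev_a, ps.prev_b])
    dipl = np.empty((n_pool, 2), dtype=np.int64)
    for s in (0, 1):
        m = sub == s
        dipl[m] = rng.choice(K, size=(int(m.sum()), 2), p=freqs[s])
    affected = rng.random(n_pool) < prevs[sub]
    case_rows = np.flatnonzero(affected)
    control_rows = np.flatnonzero(~affected)
    if len(case_rows) < scenario.n2 or len(control_rows) < scenario.n3:
        raise RuntimeError("admixed pool too small for requested n2/n3")
    pick_case = rng.choice(case_rows, size=scenario.n2, replace=False)
    pick_ctrl = rng.choice(control_rows, size=scenario.n3, replace=False)

    # trios: null within-subpopulation model => uniform transmission
    n1 = scenario.n1
    if ps.trio_source == "subpopB":
        trio_sub = np.ones(n1, dtype=np.int8)
    else:
        trio_sub = (rng.random(n1) < ps.mix[1]).astype(np.int8)
    par = np.empty((n1, 4), dtype=np.int64)
    for s in (0, 1):
        m = trio_sub == s
        par[m] = rng.choice(K, size=(int(m.sum()), 4), p=freqs[s])
    takes_A = rng.random(n1) < 0.5

    trio_ds = _trio_cohort(scenario, par, takes_A, subpop=trio_sub)
    tg = trio_ds.cohort.genotypes
    dosage = _dosage_matrix(scenario.haplotypes)
    cc_rows = np.concatenate([pick_case, pick_ctrl])
    cc_geno = _geno_from_diplotypes(dipl[cc_rows], dosage)
    cc_pheno = np.concatenate([np.ones(scenario.n2, dtype=np.int8),
                               np.zeros(scenario.n3, dtype=np.int8)])
    cc_ids = [f"case{i + 1}" for i in range(scenario.n2)] + \
             [f"ctrl{i + 1}" for i in range(scenario.n3)]
    gm = GenotypeMatrix(
        tg.sample_ids + cc_ids,
        np.vstack([tg.geno, cc_geno]),
        np.concatenate([tg.phenotype, cc_pheno]),
        tg.snp_ids,
    )
    off = tg.n_samples
    cohort = CohortData(
        genotypes=gm,
        trios=trio_ds.cohort.trios,
        unrelated_case_idx=list(range(off, off + scenario.n2)),
        unrelated_control_idx=list(range(off + scenario.n2,
                                         off + scenario.n2 + scenario.n3)),
    )
    true_dipl = np.vstack([trio_ds.true_diplotypes, dipl[cc_rows]])
    subpop = np.concatenate([trio_ds.subpopulation, sub[cc_rows]])
    return SimulatedDataset(cohort, scenario, true_dipl, subpop)


def simulate_cohort(scenario: SimulationScenario, seed=None) -> SimulatedDataset:
    """One full replicate (trios + unrelated samples) of a scenario."""
    rng = _as_rng(seed)
    if scenario.ps is not None:
        return simulate_admixed(scenario, rng)
    scenario = _ensure_alpha(scenario)
    trio_ds = simulate_trios(scenario, scenario.n1, rng)
    cc_ds = simulate_case_control(scenario, scenario.n2, scenario.n3, rng)
    tg, cg = trio_ds.cohort.genotypes, cc_ds.cohort.genotypes
    gm = GenotypeMatrix(
        tg.sample_ids + cg.sample_ids,
        np.vstack([tg.geno, cg.geno]),
        np.concatenate([tg.phenotype, cg.phenotype]),
        tg.snp_ids,
    )
    off = tg.n_samples
    cohort = CohortData(
        genotypes=gm,
        trios=trio_ds.cohort.trios,
        unrelated_case_idx=[off + i for i in cc_ds.cohort.unrelated_case_idx],
        unrelated_control_idx=[off + i
                               for i in cc_ds.cohort.unrelated_control_idx],
    )
    return SimulatedDataset(
        cohort, scenario,
        np.vstack([trio_ds.true_diplotypes, cc_ds.true_diplotypes]),
        np.concatenate([trio_ds.subpopulation, cc_ds.subpopulation]),
    )
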