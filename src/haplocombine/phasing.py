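"""EM haplotype-frequency estimation and weighted-count construction.

Two estimators are provided, one per study design:

* :func:`em_unrelated` — the classical multinomial EM under Hardy-Weinberg
  equilibrium for unphased unrelated samples.
* :func:`em_trios` — EM over parental phase/transmission configurations of
  case-parent trios, with the four parental haplotypes treated as i.i.d.
  draws from the population frequency vector (random mating).

From the fitted frequencies every (pseudo-)individual is converted to a
*weighted-count* row: the posterior-expected number of copies (0..2) of
each haplotype given the individual's genotype.  Rows always sum to 2.
For a trio, the affected child contributes the expected transmitted
counts (a case row) and the Falk-Rubenstein pseudo-control contributes
the expected non-transmitted counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import GenotypeMatrix, Haplotype, TrioRecord

__all__ = [
    "HaplotypeFrequencySet",
    "DiplotypePosterior",
    "WeightedCountRow",
    "PhasingError",
    "enumerate_compatible_diplotypes",
    "em_unrelated",
    "em_trios",
    "diplotype_posteriors",
    "weighted_counts_unrelated",
    "trio_transmission_counts",
    "trio_weighted_count_matrices",
    "weighted_count_matrix",
    "union_space",
    "extend_to_space",
]

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000


class PhasingError(RuntimeError):
    pass


@dataclass
class HaplotypeFrequencySet:
    """Estimated haplotype frequencies from one source of data."""

    haplotypes: list[Haplotype]
    freqs: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    source_label: str = ""
    loglik_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.haplotypes) != len(set(self.haplotypes)):
            raise ValueError("haplotypes must be distinct")
        if self.freqs.shape != (len(self.haplotypes),):
            raise ValueError("freqs length mismatch")
        if (self.freqs < -1e-12).any() or abs(self.freqs.sum() - 1.0) > 1e-10:
            raise ValueError("freqs must be a probability vector")

    def as_dict(self) -> dict[Haplotype, float]:
        return dict(zip(self.haplotypes, self.freqs))


@dataclass
class DiplotypePosterior:
    """Posterior over genotype-compatible haplotype pairs of one sample."""

    sample_id: str
    pairs: list[tuple[Haplotype, Haplotype]]
    probs: np.ndarray


@dataclass
class WeightedCountRow:
    """Expected haplotype dosages (summing to 2) of one analysis row."""

    counts: np.ndarray
    haplotypes: list[Haplotype]
    source: str  # trio-case | trio-pseudocontrol | cc-case | cc-control
    phenotype: int
    sample_id: str = ""


# ---------------------------------------------------------------------------
# integer haplotype codes (bit j set <=> allele 2 at SNP j)

def _code_to_haplotype(code: int, q: int) -> Haplotype:
    return Haplotype(tuple(1 + ((code >> j) & 1) for j in range(q)))


def _compatible_pair_codes(geno_row: np.ndarray) -> list[tuple[int, int]]:
    """All unordered haplotype-code pairs summing to the genotype row."""
    het = [j for j, g in enumerate(geno_row) if g == 1]
    base = sum(1 << j for j, g in enumerate(geno_row) if g == 2)
    if not het:
        return [(base, base)]
    first, rest = het[0], het[1:]
    all_het = sum(1 << j for j in het)
    pairs = []
    for mask in range(1 << len(rest)):
        a_het = sum(1 << j for k, j in enumerate(rest) if (mask >> k) & 1)
        a = base | a_het  # first het site: allele 1 on haplotype a
        b = base | (all_het & ~a_het)
        pairs.append((a, b))
    return pairs


def enumerate_compatible_diplotypes(
    geno_row: "np.ndarray | list[int]",
) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs whose dosage sum equals the genotype.

    For k heterozygous sites there are ``2**max(k-1, 0)`` resolutions.
    """
    geno_row = np.asarray(geno_row)
    if not np.isin(geno_row, (0, 1, 2)).all():
        raise ValueError(f"genotype entries must be 0/1/2, got {geno_row}")
    q = len(geno_row)
    return [
        (_code_to_haplotype(a, q), _code_to_haplotype(b, q))
        for a, b in _compatible_pair_codes(geno_row)
    ]


def union_space(*hap_lists: "list[Haplotype]") -> list[Haplotype]:
    """Sorted union of haplotype lists: the shared coordinate system."""
    out: set[Haplotype] = set()
    for hl in hap_lists:
        out.update(hl)
    return sorted(out)


def extend_to_space(hf: HaplotypeFrequencySet,
                    space: list[Haplotype]) -> HaplotypeFrequencySet:
    """Re-express frequencies in a larger space (new entries get 0)."""
    idx = {h: i for i, h in enumerate(space)}
    freqs = np.zeros(len(space))
    for h, f in zip(hf.haplotypes, hf.freqs):
        if h not in idx:
            raise ValueError(f"haplotype {h} absent from target space")
        freqs[idx[h]] = f
    return HaplotypeFrequencySet(list(space), freqs, hf.loglik, hf.n_iter,
                                 hf.converged, hf.source_label, hf.loglik_trace)


# ---------------------------------------------------------------------------
# unrelated-sample EM

@dataclass
class _UnrelatedLikelihood:
    """Deduplicated diplotype-enumeration arrays for a genotype matrix."""

    support: list[int]            # haplotype codes
    pair_a: np.ndarray            # support index of first haplotype
    pair_b: np.ndarray
    pair_grp: np.ndarray          # unique-genotype index per pair
    mult: np.ndarray              # 2 for heterozygous pairs, 1 otherwise
    grp_count: np.ndarray         # individuals per unique genotype
    grp_inverse: np.ndarray       # unique-genotype index per individual

    @property
    def n(self) -> int:
        return int(self.grp_count.sum())


def _build_unrelated(geno: np.ndarray) -> _UnrelatedLikelihood:
    uniq, inverse, counts = np.unique(geno, axis=0, return_inverse=True,
                                      return_counts=True)
    support: dict[int, int] = {}
    pa, pb, pg, mult = [], [], [], []
    for g, row in enumerate(uniq):
        for a, b in _compatible_pair_codes(row):
            for c in (a, b):
                if c not in support:
                    support[c] = len(support)
            pa.append(support[a])
            pb.append(support[b])
            pg.append(g)
            mult.append(2 if a != b else 1)
    return _UnrelatedLikelihood(
        support=list(support),
        pair_a=np.array(pa), pair_b=np.array(pb), pair_grp=np.array(pg),
        mult=np.array(mult, dtype=float),
        grp_count=counts.astype(float), grp_inverse=inverse,
    )


def _marginal_init(geno: np.ndarray, support_codes: list[int]) -> np.ndarray:
    """Product of marginal allele-2 frequencies over the support."""
    p2 = geno.mean(axis=0) / 2.0
    q = geno.shape[1]
    f = np.empty(len(support_codes))
    for i, c in enumerate(support_codes):
        bits = np.array([(c >> j) & 1 for j in range(q)])
        f[i] = np.prod(np.where(bits == 1, p2, 1.0 - p2))
    s = f.sum()
    if s <= 0:
        f = np.full(len(support_codes), 1.0 / len(support_codes))
    else:
        f = f / s
    return f


def em_unrelated(genotypes: GenotypeMatrix, tol: float = DEFAULT_TOL,
                 max_iter: int = DEFAULT_MAX_ITER, seed: int = 0,
                 source_label: str = "case-control") -> HaplotypeFrequencySet:
    """HWE multinomial EM for haplotype frequencies of unrelated samples.

    Initialisation is the deterministic product of marginal allele
    frequencies; ``seed`` is accepted for interface symmetry but unused
    unless random restarts are ever requested.  The observed-data
    log-likelihood is non-decreasing; convergence is declared when its
    increment falls below ``tol``.
    """
    if genotypes.n_samples < 1:
        raise ValueError("em_unrelated requires at least one individual")
    lik = _build_unrelated(genotypes.geno)
    f = _marginal_init(genotypes.geno, lik.support)
    trace = []
    n2 = 2.0 * lik.n
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    G = len(lik.grp_count)
    for n_iter in range(1, max_iter + 1):
        w = f[lik.pair_a] * f[lik.pair_b] * lik.mult
        S = np.bincount(lik.pair_grp, weights=w, minlength=G)
        if (S <= 0).any():
            bad = int(np.argmax(S <= 0))
            raise PhasingError(
                f"genotype class {bad} has zero likelihood under current "
                "frequencies"
            )
        ll = float(np.dot(lik.grp_count, np.log(S)))
        trace.append(ll)
        post = w / S[lik.pair_grp] * lik.grp_count[lik.pair_grp]
        f = (np.bincount(lik.pair_a, weights=post, minlength=len(f))
             + np.bincount(lik.pair_b, weights=post, minlength=len(f))) / n2
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    q = genotypes.q
    haps = [_code_to_haplotype(c, q) for c in lik.support]
    idx = sorted(range(len(haps)), key=lambda i: haps[i])
    return HaplotypeFrequencySet(
        haplotypes=[haps[i] for i in idx],
        freqs=np.maximum(f[idx], 0.0) / max(f.sum(), 1e-300),
        loglik=trace[-1], n_iter=n_iter, converged=converged,
        source_label=source_label, loglik_trace=np.array(trace),
    )


def diplotype_posteriors(genotypes: GenotypeMatrix,
                         hf: HaplotypeFrequencySet) -> list[DiplotypePosterior]:
    """Per-sample posterior over compatible diplotypes given ``hf``."""
    q = genotypes.q
    fmap = {h: f for h, f in zip(hf.haplotypes, hf.freqs)}
    out = []
    for i in range(genotypes.n_samples):
        pairs = enumerate_compatible_diplotypes(genotypes.geno[i])
        w = np.array([
            (2.0 if a != b else 1.0) * fmap.get(a, 0.0) * fmap.get(b, 0.0)
            for a, b in pairs
        ])
        tot = w.sum()
        if tot <= 0:
            raise PhasingError(
                f"sample {genotypes.sample_ids[i]}: every compatible "
                "diplotype has zero probability under the supplied "
                "frequencies"
            )
        out.append(DiplotypePosterior(genotypes.sample_ids[i], pairs, w / tot))
    return out


def weighted_count_matrix(genotypes: GenotypeMatrix,
                          hf: HaplotypeFrequencySet) -> np.ndarray:
    """Matrix of posterior-expected haplotype counts (n x len(hf))."""
    lik = _build_unrelated(genotypes.geno)
    q = genotypes.q
    idx = {h: i for i, h in enumerate(hf.haplotypes)}
    H = len(hf.haplotypes)
    fsup = np.zeros(len(lik.support))
    col = np.full(len(lik.support), -1)
    for i, c in enumerate(lik.support):
        h = _code_to_haplotype(c, q)
        if h in idx:
            col[i] = idx[h]
            fsup[i] = hf.freqs[idx[h]]
    w = fsup[lik.pair_a] * fsup[lik.pair_b] * lik.mult
    G = len(lik.grp_count)
    S = np.bincount(lik.pair_grp, weights=w, minlength=G)
    if (S <= 0).any():
        g_bad = int(np.argmax(S <= 0))
        offender = int(np.argmax(lik.grp_inverse == g_bad))
        raise PhasingError(
            f"sample {genotypes.sample_ids[offender]}: every compatible "
            "diplotype has zero probability under the supplied frequencies"
        )
    post = w / S[lik.pair_grp]
    counts_u = np.zeros((G, H))
    for side in (lik.pair_a, lik.pair_b):
        keep = col[side] >= 0
        np.add.at(counts_u, (lik.pair_grp[keep], col[side][keep]), post[keep])
    return counts_u[lik.grp_inverse]


def weighted_counts_unrelated(genotypes: GenotypeMatrix,
                              hf: HaplotypeFrequencySet,
                              ) -> list[WeightedCountRow]:
    """One weighted-count row per unrelated sample, carrying its phenotype."""
    M = weighted_count_matrix(genotypes, hf)
    rows = []
    for i in range(genotypes.n_samples):
        ph = int(genotypes.phenotype[i])
        rows.append(WeightedCountRow(
            counts=M[i], haplotypes=hf.haplotypes,
            source="cc-case" if ph == 1 else "cc-control",
            phenotype=ph, sample_id=genotypes.sample_ids[i],
        ))
    return rows


# ---------------------------------------------------------------------------
# trio EM

@dataclass
class _TrioLikelihood:
    support: list[int]
    cfg_h: np.ndarray        # (n_cfg, 4) support indices: fT, fU, mT, mU
    cfg_grp: np.ndarray      # unique-trio-genotype index per configuration
    grp_count: np.ndarray
    grp_inverse: np.ndarray

    @property
    def n(self) -> int:
        return int(self.grp_count.sum())


def _ordered_resolutions(row: np.ndarray) -> list[tuple[int, int]]:
    """Ordered (transmitted, untransmitted) resolutions of one genotype."""
    out = []
    for a, b in _compatible_pair_codes(row):
        out.append((a, b))
        if a != b:
            out.append((b, a))
    return out


def _build_trio(geno: np.ndarray, trios: list[TrioRecord]) -> _TrioLikelihood:
    sig = np.stack([
        np.concatenate([geno[t.father_row], geno[t.mother_row],
                        geno[t.child_row]])
        for t in trios
    ])
    uniq, inverse, counts = np.unique(sig, axis=0, return_inverse=True,
                                      return_counts=True)
    q = geno.shape[1]
    support: dict[int, int] = {}

    def sidx(c: int) -> int:
        if c not in support:
            support[c] = len(support)
        return support[c]

    cfg_h, cfg_grp = [], []
    for g, row in enumerate(uniq):
        gf, gm, gc = row[:q], row[q:2 * q], row[2 * q:]
        mask2 = sum(1 << j for j in range(q) if gc[j] == 2)
        mask12 = sum(1 << j for j in range(q) if gc[j] >= 1)
        found = False
        for fT, fU in _ordered_resolutions(gf):
            for mT, mU in _ordered_resolutions(gm):
                if (fT & mT) == mask2 and (fT | mT) == mask12:
                    cfg_h.append((sidx(fT), sidx(fU), sidx(mT), sidx(mU)))
                    cfg_grp.append(g)
                    found = True
        if not found:
            raise PhasingError(
                "Mendelian-inconsistent trio genotype encountered during "
                f"phasing (father={gf}, mother={gm}, child={gc})"
            )
    return _TrioLikelihood(
        support=list(support),
        cfg_h=np.array(cfg_h), cfg_grp=np.array(cfg_grp),
        grp_count=counts.astype(float), grp_inverse=inverse,
    )


def em_trios(genotypes: GenotypeMatrix, trios: list[TrioRecord],
             tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
             source_label: str = "trios") -> HaplotypeFrequencySet:
    """EM over parental phase/transmission configurations of trios.

    Each trio contributes four parental haplotype slots; configurations
    are all (father resolution, mother resolution, transmission) triples
    reproducing both parents' and the child's genotypes, weighted by the
    HWE product of the four haplotype frequencies.
    """
    if not trios:
        raise ValueError("em_trios requires at least one trio")
    lik = _build_trio(genotypes.geno, trios)
    geno_par = np.concatenate([
        genotypes.geno[[t.father_row for t in trios]],
        genotypes.geno[[t.mother_row for t in trios]],
    ])
    f = _marginal_init(geno_par, lik.support)
    trace = []
    prev_ll = -np.inf
    converged = False
    G = len(lik.grp_count)
    n4 = 4.0 * lik.n
    H = len(lik.support)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = f[lik.cfg_h].prod(axis=1)
        S = np.bincount(lik.cfg_grp, weights=w, minlength=G)
        if (S <= 0).any():
            raise PhasingError("trio genotype with zero likelihood")
        ll = float(np.dot(lik.grp_count, np.log(S)))
        trace.append(ll)
        post = w / S[lik.cfg_grp] * lik.grp_count[lik.cfg_grp]
        f_new = np.zeros(H)
        for k in range(4):
            f_new += np.bincount(lik.cfg_h[:, k], weights=post, minlength=H)
        f = f_new / n4
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    q = genotypes.q
    haps = [_code_to_haplotype(c, q) for c in lik.support]
    idx = sorted(range(len(haps)), key=lambda i: haps[i])
    return HaplotypeFrequencySet(
        haplotypes=[haps[i] for i in idx],
        freqs=np.maximum(f[idx], 0.0) / max(f.sum(), 1e-300),
        loglik=trace[-1], n_iter=n_iter, converged=converged,
        source_label=source_label, loglik_trace=np.array(trace),
    )


def trio_weighted_count_matrices(
    genotypes: GenotypeMatrix, trios: list[TrioRecord],
    hf: HaplotypeFrequencySet,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected transmitted / non-transmitted count matrices (n1 x H)."""
    lik = _build_trio(genotypes.geno, trios)
    q = genotypes.q
    idx = {h: i for i, h in enumerate(hf.haplotypes)}
    H = len(hf.haplotypes)
    fsup = np.zeros(len(lik.support))
    col = np.full(len(lik.support), -1)
    for i, c in enumerate(lik.support):
        h = _code_to_haplotype(c, q)
        if h in idx:
            col[i] = idx[h]
            fsup[i] = hf.freqs[idx[h]]
    w = fsup[lik.cfg_h].prod(axis=1)
    G = len(lik.grp_count)
    S = np.bincount(lik.cfg_grp, weights=w, minlength=G)
    if (S <= 0).any():
        raise PhasingError(
            "trio with zero probability under the supplied frequencies"
        )
    post = w / S[lik.cfg_grp]
    case_u = np.zeros((G, H))
    pseudo_u = np.zeros((G, H))
    for k, target in ((0, case_u), (1, pseudo_u), (2, case_u), (3, pseudo_u)):
        cc = col[lik.cfg_h[:, k]]
        keep = cc >= 0
        np.add.at(target, (lik.cfg_grp[keep], cc[keep]), post[keep])
    return case_u[lik.grp_inverse], pseudo_u[lik.grp_inverse]


def trio_transmission_counts(
    genotypes: GenotypeMatrix, trio: TrioRecord, hf: HaplotypeFrequencySet,
) -> tuple[WeightedCountRow, WeightedCountRow]:
    """Case and pseudo-control weighted-count rows for one trio."""
    case_m, pseudo_m = trio_weighted_count_matrices(genotypes, [trio], hf)
    child_id = genotypes.sample_ids[trio.child_row]
    case = WeightedCountRow(case_m[0], hf.haplotypes, "trio-case", 1,
                            child_id)
    pseudo = WeightedCountRow(pseudo_m[0], hf.haplotypes,
                              "trio-pseudocontrol", 0, child_id + ":pseudo")
    return case, pseudo
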