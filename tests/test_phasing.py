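import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from haplocombine.datamodel import Haplotype, TrioRecord
from haplocombine.phasing import (
    HaplotypeFrequencySet,
    PhasingError,
    diplotype_posteriors,
    em_trios,
    em_unrelated,
    enumerate_compatible_diplotypes,
    extend_to_space,
    trio_transmission_counts,
    trio_weighted_count_matrices,
    union_space,
    weighted_count_matrix,
    weighted_counts_unrelated,
)

from conftest import H, make_genotypes


def all_haplotypes(q):
    return [Haplotype(a) for a in itertools.product((1, 2), repeat=q)]


def brute_force_pairs(geno):
    """All unordered haplotype pairs summing to the genotype, by scan."""
    q = len(geno)
    out = set()
    for a in all_haplotypes(q):
        for b in all_haplotypes(q):
            if all(da + db == g for da, db, g in
                   zip(a.dosage, b.dosage, geno)):
                out.add(frozenset((a, b)) if a != b else frozenset((a,)))
    return out


class TestEnumerateDiplotypes:
    def test_fully_homozygous(self):
        pairs = enumerate_compatible_diplotypes([2, 0])
        assert pairs == [(H("2-1"), H("2-1"))]

    def test_double_heterozygote(self):
        pairs = {frozenset(p) for p in enumerate_compatible_diplotypes([1, 1])}
        assert pairs == {frozenset((H("1-1"), H("2-2"))),
                         frozenset((H("1-2"), H("2-1")))}

    @pytest.mark.parametrize("geno", [
        (1, 1, 1, 0, 2), (1, 0, 1, 1, 1), (2, 1, 1, 1, 1), (0, 0, 0, 0, 0),
    ])
    def test_against_brute_force_scan_q5(self, geno):
        got = {frozenset(p) if p[0] != p[1] else frozenset((p[0],))
               for p in enumerate_compatible_diplotypes(geno)}
        assert got == brute_force_pairs(geno)
        k = sum(g == 1 for g in geno)
        assert len(got) == 2 ** max(k - 1, 0)

    def test_invalid_entry_rejected(self):
        with pytest.raises(ValueError):
            enumerate_compatible_diplotypes([0, 3])


def direct_loglik_unrelated(geno_rows, haps, freqs):
    """Observed-data log-likelihood by explicit enumeration."""
    fmap = dict(zip(haps, freqs))
    ll = 0.0
    for row in geno_rows:
        s = 0.0
        for a, b in enumerate_compatible_diplotypes(row):
            mult = 2.0 if a != b else 1.0
            s += mult * fmap.get(a, 0.0) * fmap.get(b, 0.0)
        ll += np.log(s)
    return ll


class TestEMUnrelated:
    def test_all_homozygous_gives_degenerate_frequency(self):
        gm = make_genotypes([[0, 0]] * 5)
        hf = em_unrelated(gm)
        assert hf.as_dict()[H("1-1")] == pytest.approx(1.0)

    def test_two_individual_instance_matches_grid_search(self):
        # individuals (0,0) and (1,1): likelihood p11^2 (2 p11 p22 + 2 p12 p21)
        # grid search over the simplex gives p11=0.75, p22=0.25
        gm = make_genotypes([[0, 0], [1, 1]])
        hf = em_unrelated(gm, tol=1e-12, max_iter=5000)
        d = hf.as_dict()
        assert d[H("1-1")] == pytest.approx(0.75, abs=2e-3)
        assert d[H("2-2")] == pytest.approx(0.25, abs=2e-3)
        assert d.get(H("1-2"), 0.0) == pytest.approx(0.0, abs=2e-3)

    def test_recovers_frequencies_from_large_sample(self):
        rng = np.random.default_rng(11)
        haps = [H("1-1"), H("1-2"), H("2-1"), H("2-2")]
        truth = np.array([0.5, 0.1, 0.3, 0.1])
        dos = np.array([h.dosage for h in haps])
        dip = rng.choice(4, size=(1000, 2), p=truth)
        gm = make_genotypes(dos[dip[:, 0]] + dos[dip[:, 1]])
        hf = em_unrelated(gm)
        est = np.array([hf.as_dict().get(h, 0.0) for h in haps])
        assert np.abs(est - truth).max() < 0.03

    def test_loglik_is_monotone(self):
        rng = np.random.default_rng(3)
        gm = make_genotypes(rng.integers(0, 3, size=(40, 3)))
        hf = em_unrelated(gm)
        diffs = np.diff(hf.loglik_trace)
        assert (diffs >= -1e-9).all()
        assert hf.converged

    def test_matches_direct_numerical_maximization(self):
        # <= 4 haplotypes: maximize over the simplex with a generic optimizer
        rng = np.random.default_rng(8)
        gm = make_genotypes(rng.integers(0, 3, size=(30, 2)))
        hf = em_unrelated(gm, tol=1e-12, max_iter=5000)
        haps = all_haplotypes(2)

        def neg_ll(x):
            w = np.exp(x - x.max())
            f = w / w.sum()
            return -direct_loglik_unrelated(gm.geno, haps, f)

        best = min(
            (minimize(neg_ll, rng.normal(size=4), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12,
                               "maxiter": 20000})
             for _ in range(3)),
            key=lambda r: r.fun,
        )
        assert hf.loglik == pytest.approx(-best.fun, abs=1e-6)

    def test_nonconvergence_is_flagged(self):
        gm = make_genotypes([[0, 0], [1, 1]])
        hf = em_unrelated(gm, tol=0.0, max_iter=2)  # tol 0: never satisfied
        assert not hf.converged
        assert hf.n_iter == 2


class TestWeightedCountsUnrelated:
    def test_unambiguous_genotype_gives_integer_counts(self, two_snp_haps):
        hf = HaplotypeFrequencySet(two_snp_haps, [0.5, 0.1, 0.3, 0.1],
                                   0.0, 1, True)
        gm = make_genotypes([[2, 0]], [1])
        rows = weighted_counts_unrelated(gm, hf)
        d = dict(zip(map(str, hf.haplotypes), rows[0].counts))
        assert d == {"1-1": 0, "1-2": 0, "2-1": 2, "2-2": 0}

    def test_double_heterozygote_posterior_hand_computed(self, two_snp_haps):
        # HWE pair probabilities 2*0.5*0.1 = 0.10 and 2*0.1*0.3 = 0.06
        hf = HaplotypeFrequencySet(two_snp_haps, [0.5, 0.1, 0.3, 0.1],
                                   0.0, 1, True)
        gm = make_genotypes([[1, 1]], [0])
        post = diplotype_posteriors(gm, hf)[0]
        probs = {frozenset(p): w for p, w in zip(post.pairs, post.probs)}
        assert probs[frozenset((H("1-1"), H("2-2")))] == pytest.approx(0.625)
        assert probs[frozenset((H("1-2"), H("2-1")))] == pytest.approx(0.375)
        counts = weighted_counts_unrelated(gm, hf)[0].counts
        np.testing.assert_allclose(counts, [0.625, 0.375, 0.375, 0.625])

    def test_zero_probability_individual_raises(self, two_snp_haps):
        hf = HaplotypeFrequencySet(two_snp_haps, [1.0, 0.0, 0.0, 0.0],
                                   0.0, 1, True)
        gm = make_genotypes([[2, 2]], [0])
        with pytest.raises(PhasingError, match="s1"):
            weighted_counts_unrelated(gm, hf)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_always_sum_to_two(self, seed):
        rng = np.random.default_rng(seed)
        q = int(rng.integers(1, 5))
        gm = make_genotypes(rng.integers(0, 3, size=(12, q)))
        hf = em_unrelated(gm)
        M = weighted_count_matrix(gm, hf)
        np.testing.assert_allclose(M.sum(axis=1), 2.0, atol=1e-9)
        assert (M >= -1e-12).all() and (M <= 2 + 1e-12).all()

    def test_single_snp_counts_are_integer_allele_counts(self):
        gm = make_genotypes([[0], [1], [2], [1]])
        hf = em_unrelated(gm)
        M = weighted_count_matrix(gm, hf)
        col2 = [str(h) for h in hf.haplotypes].index("2")
        np.testing.assert_allclose(M[:, col2], [0, 1, 2, 1], atol=1e-12)


def make_trio_cohort(gf, gm_, gc):
    geno = np.array([gf, gm_, gc])
    g = make_genotypes(geno, [-1, -1, 1])
    return g, [TrioRecord(0, 1, 2)]


def trio_config_oracle(gf, gm_, gc, haps, freqs):
    """Exhaustive (father phase, mother phase, transmission) enumeration."""
    fmap = dict(zip(haps, freqs))
    q = len(gf)

    def ordered(geno):
        out = []
        for a, b in enumerate_compatible_diplotypes(geno):
            out.append((a, b))
            if a != b:
                out.append((b, a))
        return out

    configs = []
    for fT, fU in ordered(gf):
        for mT, mU in ordered(gm_):
            if all(dt + dm == g for dt, dm, g in
                   zip(fT.dosage, mT.dosage, gc)):
                w = (fmap.get(fT, 0) * fmap.get(fU, 0)
                     * fmap.get(mT, 0) * fmap.get(mU, 0))
                configs.append(((fT, fU, mT, mU), w))
    tot = sum(w for _, w in configs)
    case = {h: 0.0 for h in haps}
    pseudo = {h: 0.0 for h in haps}
    for (fT, fU, mT, mU), w in configs:
        case[fT] += w / tot
        case[mT] += w / tot
        pseudo[fU] += w / tot
        pseudo[mU] += w / tot
    return case, pseudo, tot


class TestEMTrios:
    def test_fully_determined_trio(self):
        g, trios = make_trio_cohort([0, 0], [2, 2], [1, 1])
        hf = em_trios(g, trios)
        d = hf.as_dict()
        assert d[H("1-1")] == pytest.approx(0.5)
        assert d[H("2-2")] == pytest.approx(0.5)

    def test_recovers_frequencies_from_many_trios(self):
        from haplocombine.simulate import SimulationScenario, simulate_trios

        haps = [H("1-1"), H("1-2"), H("2-1"), H("2-2")]
        truth = np.array([0.4, 0.3, 0.15, 0.15])
        sc = SimulationScenario("custom", haps, truth, np.ones(4), haps[0])
        ds = simulate_trios(sc, 200, seed=21)
        hf = em_trios(ds.cohort.genotypes, ds.cohort.trios)
        est = np.array([hf.as_dict().get(h, 0.0) for h in haps])
        assert np.abs(est - truth).max() < 0.05
        assert (np.diff(hf.loglik_trace) >= -1e-9).all()

    def test_all_heterozygous_trio_is_em_stationary_point(self):
        # the EM solution must be a stationary point of the exhaustively
        # enumerated configuration likelihood
        g, trios = make_trio_cohort([1, 1], [1, 1], [1, 1])
        hf = em_trios(g, trios, tol=1e-14, max_iter=10000)
        haps = all_haplotypes(2)
        freqs = np.array([hf.as_dict().get(h, 0.0) for h in haps])
        # one more exact EM step using the oracle must not move frequencies
        case, pseudo, _ = trio_config_oracle([1, 1], [1, 1], [1, 1],
                                             haps, freqs)
        updated = np.array([(case[h] + pseudo[h]) / 4.0 for h in haps])
        np.testing.assert_allclose(freqs, updated, atol=1e-6)

    def test_inconsistent_trio_raises(self):
        g = make_genotypes([[0, 0], [0, 0], [2, 0]], [-1, -1, 1])
        with pytest.raises(PhasingError):
            em_trios(g, [TrioRecord(0, 1, 2)])


class TestTrioTransmissionCounts:
    def test_mendelian_resolution_forces_transmission(self, two_snp_haps):
        g, trios = make_trio_cohort([1, 0], [0, 0], [0, 0])
        hf = HaplotypeFrequencySet(two_snp_haps, [0.5, 0.1, 0.3, 0.1],
                                   0.0, 1, True)
        case, pseudo = trio_transmission_counts(g, trios[0], hf)
        c = dict(zip(map(str, two_snp_haps), case.counts))
        p = dict(zip(map(str, two_snp_haps), pseudo.counts))
        assert c == {"1-1": 2, "1-2": 0, "2-1": 0, "2-2": 0}
        assert p == {"1-1": 1, "1-2": 0, "2-1": 1, "2-2": 0}
        assert case.phenotype == 1 and pseudo.phenotype == 0

    def test_uninformative_trio(self, two_snp_haps):
        g, trios = make_trio_cohort([0, 0], [0, 0], [0, 0])
        hf = HaplotypeFrequencySet(two_snp_haps, [0.5, 0.1, 0.3, 0.1],
                                   0.0, 1, True)
        case, pseudo = trio_transmission_counts(g, trios[0], hf)
        np.testing.assert_allclose(case.counts, [2, 0, 0, 0])
        np.testing.assert_allclose(pseudo.counts, [2, 0, 0, 0])

    def test_all_heterozygous_trio_matches_config_oracle(self, two_snp_haps):
        g, trios = make_trio_cohort([1, 1], [1, 1], [1, 1])
        freqs = [0.5, 0.1, 0.3, 0.1]
        hf = HaplotypeFrequencySet(two_snp_haps, freqs, 0.0, 1, True)
        case, pseudo = trio_transmission_counts(g, trios[0], hf)
        oc, op, _ = trio_config_oracle([1, 1], [1, 1], [1, 1],
                                       two_snp_haps, freqs)
        np.testing.assert_allclose(
            case.counts, [oc[h] for h in two_snp_haps], atol=1e-12)
        np.testing.assert_allclose(
            pseudo.counts, [op[h] for h in two_snp_haps], atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_case_plus_pseudo_covers_four_parental_slots(self, seed):
        from haplocombine.simulate import SimulationScenario, simulate_trios

        rng = np.random.default_rng(seed)
        haps = all_haplotypes(2)
        f = rng.dirichlet(np.ones(4))
        sc = SimulationScenario("c", haps, f, np.ones(4), haps[0])
        ds = simulate_trios(sc, 8, seed=rng.integers(1 << 30))
        hf = em_trios(ds.cohort.genotypes, ds.cohort.trios)
        space = hf.haplotypes
        tc, tp = trio_weighted_count_matrices(
            ds.cohort.genotypes, ds.cohort.trios, hf)
        np.testing.assert_allclose(tc.sum(axis=1), 2.0, atol=1e-9)
        np.testing.assert_allclose(tp.sum(axis=1), 2.0, atol=1e-9)
        np.testing.assert_allclose((tc + tp).sum(axis=1), 4.0, atol=1e-9)


class TestSpaceHandling:
    def test_union_space_sorted_distinct(self):
        sp = union_space([H("2-1"), H("1-1")], [H("1-1"), H("1-2")])
        assert sp == [H("1-1"), H("1-2"), H("2-1")]

    def test_extend_preserves_mass(self, two_snp_haps):
        hf = HaplotypeFrequencySet([H("1-1"), H("2-2")], [0.7, 0.3],
                                   0.0, 1, True)
        ext = extend_to_space(hf, two_snp_haps)
        assert ext.as_dict()[H("1-1")] == 0.7
        assert ext.as_dict()[H("1-2")] == 0.0
        assert ext.freqs.sum() == pytest.approx(1.0)
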