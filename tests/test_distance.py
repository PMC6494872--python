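"""Model distances, Phi-st, permutation tests and non-metric MDS."""

import math

import numpy as np
import pytest
from scipy.stats import kstest, spearmanr

from mttransect.distance import (
    SaturationError,
    SubstitutionModel,
    fst_permutation_p,
    nmds,
    pairwise_distance,
    pairwise_fst,
    slatkin_linearize,
)

P = SubstitutionModel(model="P_DIST")
JC = SubstitutionModel(model="JC69")
K2P = SubstitutionModel(model="K2P")


class TestPairwiseDistance:
    def test_p_distance(self):
        assert pairwise_distance("ACGT", "ACGA", P) == pytest.approx(0.25)

    def test_jc69_closed_form(self):
        # p = 0.25 -> d = -(3/4) ln(1 - 1/3) = 0.30409...
        d = pairwise_distance("AAAA", "AAAT", JC)
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.25 / 3), abs=1e-9)
        assert d == pytest.approx(0.30409, abs=1e-5)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            pairwise_distance("AAAA", "TTTT", JC)  # p = 1 > 3/4

    def _jc_pattern_pair(self, rng, L=240, m=24):
        """Random pair whose mismatch patterns follow exact equal-input
        proportions: transitions A<->G, C<->T and transversions at 1:1:4."""
        base = rng.choice(list("ACGT"), size=L)
        other = base.copy()
        sites = rng.choice(L, size=m, replace=False)
        k = m // 6
        for i in sites[:k]:
            base[i], other[i] = "A", "G"
        for i in sites[k : 2 * k]:
            base[i], other[i] = "C", "T"
        tv = [("A", "C"), ("A", "T"), ("G", "C"), ("G", "T")]
        for j, i in enumerate(sites[2 * k :]):
            x, y = tv[j % 4]
            base[i], other[i] = x, y
        return "".join(base), "".join(other)

    def test_tn93_and_k2p_reduce_to_jc_at_equal_rates(self):
        rng = np.random.default_rng(3)
        tn = SubstitutionModel(model="TN93", base_freqs=(0.25, 0.25, 0.25, 0.25))
        for _ in range(10):
            a, b = self._jc_pattern_pair(rng)
            d_jc = pairwise_distance(a, b, JC)
            assert pairwise_distance(a, b, tn) == pytest.approx(d_jc, abs=1e-9)
            assert pairwise_distance(a, b, K2P) == pytest.approx(d_jc, abs=1e-9)

    def test_gamma_correction_converges_to_plain_log_form(self):
        jc_g = SubstitutionModel(model="JC69", gamma_alpha=1e7)
        d = pairwise_distance("AAAAAAAA", "AAAAAATT", JC)
        dg = pairwise_distance("AAAAAAAA", "AAAAAATT", jc_g)
        assert dg == pytest.approx(d, rel=1e-5)

    def test_gamma_inflates_large_distances(self):
        jc_g = SubstitutionModel(model="JC69", gamma_alpha=0.5)
        a, b = "AAAAAAAAAA", "AAAAAATTTT"
        assert pairwise_distance(a, b, jc_g) > pairwise_distance(a, b, JC)

    def test_missing_sites_deleted_pairwise(self):
        assert pairwise_distance("ACGN", "ACTT", P) == pytest.approx(1 / 3)
        assert pairwise_distance("ACG-", "ACTT", P) == pytest.approx(1 / 3)

    def test_fifth_state_counts_gaps(self):
        fifth = SubstitutionModel(model="P_DIST", gap_mode="fifth_state")
        assert pairwise_distance("ACG-", "ACTT", fifth) == pytest.approx(0.5)

    def test_fifth_state_restricted_to_p_distance(self):
        with pytest.raises(ValueError):
            SubstitutionModel(model="JC69", gap_mode="fifth_state")

    def test_symmetry_and_zero_on_identity(self):
        rng = np.random.default_rng(9)
        for model in (P, JC, K2P):
            s = list(rng.choice(list("ACGT"), size=50))
            t = s.copy()
            for i in rng.choice(50, size=5, replace=False):
                t[i] = rng.choice([b for b in "ACGT" if b != s[i]])
            s, t = "".join(s), "".join(t)
            assert pairwise_distance(s, s, model) == 0.0
            assert pairwise_distance(s, t, model) == pairwise_distance(t, s, model)


def fst_oracle(pop_a, pop_b, model):
    """Independent two-level variance decomposition with explicit loops."""
    seqs = list(pop_a) + list(pop_b)
    n1, n2 = len(pop_a), len(pop_b)
    N, Ppop = n1 + n2, 2

    def d2(i, j):
        return pairwise_distance(seqs[i], seqs[j], model) ** 2

    ss_total = sum(d2(i, j) for i in range(N) for j in range(i + 1, N)) / N
    ss_w = (
        sum(d2(i, j) for i in range(n1) for j in range(i + 1, n1)) / n1
        + sum(d2(i, j) for i in range(n1, N) for j in range(i + 1, N)) / n2
    )
    ms_w = ss_w / (N - Ppop)
    ms_a = (ss_total - ss_w) / (Ppop - 1)
    n_c = (N - (n1**2 + n2**2) / N) / (Ppop - 1)
    sigma_a = (ms_a - ms_w) / n_c
    total = sigma_a + ms_w
    return sigma_a / total if total else 0.0


class TestFst:
    def test_fixed_difference_between_monomorphic_pops(self):
        res = pairwise_fst(["AAAA"] * 3, ["AAAT"] * 3, P)
        assert res.fst == pytest.approx(1.0)

    def test_identical_haplotype_multisets_truncate_to_zero(self):
        pop = ["AAAA", "AATT", "TTTT"]
        res = pairwise_fst(pop, list(pop), P)
        assert res.fst == 0.0
        assert res.fst_raw <= 0.0

    def test_matches_independent_ssq_oracle_on_toys(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            pa = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(3)]
            pb = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(4)]
            res = pairwise_fst(pa, pb, P)
            assert res.fst_raw == pytest.approx(fst_oracle(pa, pb, P), abs=1e-10)

    def test_invariant_under_within_population_reordering(self):
        rng = np.random.default_rng(2)
        pa = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(4)]
        pb = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(4)]
        r1 = pairwise_fst(pa, pb, P)
        r2 = pairwise_fst(pa[::-1], pb[::-1], P)
        assert r1.fst_raw == pytest.approx(r2.fst_raw)

    def test_population_size_minimum_enforced(self):
        with pytest.raises(ValueError):
            pairwise_fst(["AAAA"], ["AAAT", "AATT"], P)


class TestPermutationP:
    def test_identical_populations_give_large_p(self):
        pop = ["AAAA", "AATT", "TTTT", "ACGT"]
        p = fst_permutation_p(pop, list(pop), P, n_perm=999, seed=5)
        assert p >= 0.5

    def test_fixed_difference_gives_small_p(self):
        p = fst_permutation_p(["AAAA"] * 4, ["AAAT"] * 4, P, n_perm=999, seed=5)
        # only the 2 label splits out of C(8,4)=70 that separate the
        # haplotypes reach the observed value
        assert p <= 0.05

    def test_reproducible_under_fixed_seed(self):
        pa = ["AAAA", "AATT", "ACGT", "TTTT"]
        pb = ["AAAT", "AATA", "ACGA", "TTTA"]
        p1 = fst_permutation_p(pa, pb, P, n_perm=200, seed=7)
        p2 = fst_permutation_p(pa, pb, P, n_perm=200, seed=7)
        assert p1 == p2
        assert 1 / 201 <= p1 <= 1.0

    def test_null_p_values_are_uniform(self):
        # 200 null datasets: both populations drawn from one pool
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(200):
            pool = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(16)]
            pvals.append(
                fst_permutation_p(
                    pool[:8], pool[8:], P, n_perm=99,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestSlatkin:
    @pytest.mark.parametrize("fst,d", [(0.5, 1.0), (0.0, 0.0), (0.2, 0.25)])
    def test_linearization(self, fst, d):
        assert slatkin_linearize(fst) == pytest.approx(d)

    def test_unit_fst_maps_to_infinity(self):
        assert math.isinf(slatkin_linearize(1.0))


class TestNmds:
    def test_exactly_embeddable_triple_has_zero_stress(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        emb = nmds(D, k=2, n_starts=4, seed=0)
        assert emb.stress < 1e-6
        assert emb.coordinates.shape == (3, 2)

    def test_rank_order_preserved_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        emb1 = nmds(D, k=2, seed=0)
        emb2 = nmds(np.exp(D) - 1, k=2, seed=0)  # strictly increasing transform
        iu = np.triu_indices(8, 1)

        def dists(e):
            Y = e.coordinates
            return np.sqrt(((Y[:, None] - Y[None]) ** 2).sum(-1))[iu]

        rho1 = spearmanr(dists(emb1), D[iu]).statistic
        rho2 = spearmanr(dists(emb2), D[iu]).statistic
        assert rho1 > 0.9 and rho2 > 0.9

    def test_deterministic_under_fixed_seed(self):
        D = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]], float)
        a = nmds(D, k=2, seed=3)
        b = nmds(D, k=2, seed=3)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nmds(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            nmds(np.array([[0.0, -1.0], [-1.0, 0.0]]))
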