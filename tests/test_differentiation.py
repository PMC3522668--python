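"""Differentiation estimators against hand-coded oracles and limit cases."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from conftest import make_diploid_table
from zebramhc import differentiation as diff
from zebramhc import diversity as div
from zebramhc.errors import UndefinedStatisticError
from zebramhc.io import LocusAlignment


# -- Weir & Cockerham --------------------------------------------------------

def oracle_wc_theta(pop_calls):
    """Independent route: indicator-variable ANOVA mean squares (MSP/MSI/MSG)."""
    alleles = sorted({a for calls in pop_calls for c in calls for a in c})
    r = len(pop_calls)
    n_i = [len(c) for c in pop_calls]
    N = sum(n_i)
    nc = (N - sum(n**2 for n in n_i) / N) / (r - 1)
    a_sum = abc_sum = 0.0
    for allele in alleles:
        # x[pop][ind][copy]: allele indicator per gene copy
        x = [[[float(c[0] == allele), float(c[1] == allele)] for c in calls]
             for calls in pop_calls]
        grand = sum(v for p in x for ind in p for v in ind) / (2 * N)
        pop_means = [sum(v for ind in p for v in ind) / (2 * len(p)) for p in x]
        ind_means = [[(ind[0] + ind[1]) / 2 for ind in p] for p in x]
        ssp = sum(2 * n * (pm - grand) ** 2 for n, pm in zip(n_i, pop_means))
        ssi = sum(
            2 * (im - pm) ** 2
            for p, pm in zip(ind_means, pop_means)
            for im in p
        )
        ssg = sum(
            (v - im) ** 2
            for p, pi in zip(x, ind_means)
            for ind, im in zip(p, pi)
            for v in ind
        )
        msp = ssp / (r - 1)
        msi = ssi / (N - r)
        msg = ssg / N
        a = (msp - msi) / (2 * nc)
        b = (msi - msg) / 2
        c = msg
        a_sum += a
        abc_sum += a + b + c
    return a_sum / abc_sum


class TestWCFst:
    def test_three_individual_toy_matches_anova_oracle(self):
        pop_calls = [
            [("A", "A"), ("A", "B")],
            [("B", "B")],
        ]
        a, b, c = diff._wc_components_locus(pop_calls)
        assert a / (a + b + c) == pytest.approx(oracle_wc_theta(pop_calls), abs=1e-12)

    def test_random_toys_match_anova_oracle(self, rng):
        alleles = ["x", "y", "z"]
        for _ in range(20):
            pop_calls = [
                [tuple(sorted(rng.choice(alleles, 2))) for _ in range(int(rng.integers(2, 6)))]
                for _ in range(2)
            ]
            flat = {a for calls in pop_calls for c in calls for a in c}
            if len(flat) < 2:
                continue
            a, b, c = diff._wc_components_locus(pop_calls)
            assert a / (a + b + c) == pytest.approx(
                oracle_wc_theta(pop_calls), abs=1e-10
            )

    def test_fixed_differences_approach_one(self):
        pop_calls = [[("A", "A")] * 50, [("B", "B")] * 50]
        a, b, c = diff._wc_components_locus(pop_calls)
        assert a / (a + b + c) > 0.98

    def test_panmictic_split_centred_at_zero(self, rng):
        # random halves of one pool: mean theta near 0
        thetas = []
        for _ in range(200):
            copies = rng.choice(["a", "b", "c"], size=80, p=[0.5, 0.3, 0.2])
            calls = [tuple(sorted(copies[2 * i:2 * i + 2])) for i in range(40)]
            order = rng.permutation(40)
            pop_calls = [[calls[i] for i in order[:20]], [calls[i] for i in order[20:]]]
            a, b, c = diff._wc_components_locus(pop_calls)
            if a + b + c != 0:
                thetas.append(a / (a + b + c))
        assert abs(np.mean(thetas)) < 0.01


# -- K2P ---------------------------------------------------------------------

class TestK2P:
    def test_identical(self):
        assert diff.k2p_distance("ACGT", "ACGT") == 0.0

    def test_one_transition_in_four(self):
        assert diff.k2p_distance("AAAA", "AAAG") == pytest.approx(
            -0.5 * math.log(0.5), abs=1e-12
        )

    def test_saturation_flag(self):
        with pytest.warns(UserWarning):
            d = diff.k2p_distance("AAAA", "AACC")
        assert d == math.inf

    def test_gaps_excluded_pairwise(self):
        assert diff.k2p_distance("A-AA", "AAAG", frozenset({1})) == pytest.approx(
            -0.5 * math.log(1 - 2 / 3), abs=1e-12
        )


# -- AMOVA -------------------------------------------------------------------

def oracle_amova(copy_alleles_by_pop, d2_lookup):
    """Hand-coded sums of squares on explicit gene-copy lists."""
    all_copies = [a for p in copy_alleles_by_pop for a in p]
    N = len(all_copies)
    P = len(copy_alleles_by_pop)
    ss_t = sum(
        d2_lookup[(a, b)] for a, b in itertools.combinations(all_copies, 2)
    ) / N
    ss_w = sum(
        sum(d2_lookup[(a, b)] for a, b in itertools.combinations(p, 2)) / len(p)
        for p in copy_alleles_by_pop
    )
    sigma_w = ss_w / (N - P)
    ms_a = (ss_t - ss_w) / (P - 1)
    n_prime = (N - sum(len(p) ** 2 for p in copy_alleles_by_pop) / N) / (P - 1)
    sigma_a = (ms_a - sigma_w) / n_prime
    return sigma_a / (sigma_a + sigma_w)


class TestAmova:
    def test_six_copy_toy_matches_ss_oracle(self):
        aln = LocusAlignment(
            "t", ["u", "v", "w"], ["AAAAAAAA", "AAAAAAAG", "AAAAAGGG"]
        )
        copies = [["u", "u", "v", "v"], ["w", "w", "v", "u"]]
        d2 = {}
        for x, y in itertools.product("uvw", repeat=2):
            d2[(x, y)] = 0.0 if x == y else diff.k2p_distance(
                aln.sequence(x), aln.sequence(y)
            )
        expected = oracle_amova(copies, d2)
        table, pm = make_diploid_table(
            {"p1": [("u", "u"), ("v", "v")], "p2": [("w", "w"), ("u", "v")]}
        )
        res = diff.phi_st_amova(aln, table, pm, "L", distance="k2p", n_perm=0)
        assert res.phi_st == pytest.approx(expected, abs=1e-12)

    def test_identity_distance_equals_spectrum_fst(self, rng):
        # AMOVA with 0/1 distances must equal the direct frequency computation
        table, pm = make_diploid_table(
            {
                "p1": [("a", "b"), ("a", "a"), ("b", "c"), ("a", "c")],
                "p2": [("c", "c"), ("b", "c"), ("c", "c")],
            }
        )
        res = diff.phi_st_amova(None, table, pm, "L", distance="identity", n_perm=0)
        spectra = [
            div.allele_frequencies(table, pm, "L", p) for p in ("p1", "p2")
        ]
        assert res.phi_st == pytest.approx(
            diff.haplotype_fst_from_spectra(spectra), abs=1e-10
        )

    def test_fixed_distant_haplotypes_approach_one(self):
        aln = LocusAlignment("t", ["u", "v"], ["A" * 40, "A" * 30 + "G" * 10])
        table, pm = make_diploid_table(
            {"p1": [("u", "u")] * 20, "p2": [("v", "v")] * 20}
        )
        res = diff.phi_st_amova(aln, table, pm, "L", distance="k2p", n_perm=0)
        assert res.phi_st > 0.95

    def test_identical_spectra_near_zero(self, rng):
        table, pm = make_diploid_table(
            {"p1": [("a", "b")] * 10, "p2": [("a", "b")] * 10}
        )
        res = diff.phi_st_amova(None, table, pm, "L", distance="identity", n_perm=99, rng=rng)
        assert abs(res.phi_st) < 1e-9 or res.phi_st < 0.05
        assert res.p > 0.1


# -- Jost's D ----------------------------------------------------------------

def oracle_jost(counts1, counts2):
    """Direct evaluation of the Nei–Chesser/Jost estimator formulas."""
    n1, n2 = sum(counts1.values()), sum(counts2.values())
    alleles = set(counts1) | set(counts2)
    p1 = {a: counts1.get(a, 0) / n1 for a in alleles}
    p2 = {a: counts2.get(a, 0) / n2 for a in alleles}
    n_harm = 2 / (1 / n1 + 1 / n2)
    hs_plug = 1 - (sum(v**2 for v in p1.values()) + sum(v**2 for v in p2.values())) / 2
    hs = n_harm / (n_harm - 1) * hs_plug
    ht_plug = 1 - sum(((p1[a] + p2[a]) / 2) ** 2 for a in alleles)
    ht = ht_plug + hs / (2 * n_harm)
    return 2 * (ht - hs) / (1 - hs)


class TestJostD:
    def test_equal_spectra_near_zero(self):
        s1 = div.AlleleFrequencySpectrum("L", "p1", {"a": 30, "b": 20})
        s2 = div.AlleleFrequencySpectrum("L", "p2", {"a": 30, "b": 20})
        assert diff.jost_dest([s1, s2]) == pytest.approx(0.0, abs=0.02)

    def test_fixed_different_alleles_approach_one(self):
        s1 = div.AlleleFrequencySpectrum("L", "p1", {"a": 500})
        s2 = div.AlleleFrequencySpectrum("L", "p2", {"b": 500})
        assert diff.jost_dest([s1, s2]) == pytest.approx(1.0, abs=0.01)

    def test_two_allele_toy_matches_direct_formula(self):
        c1, c2 = {"a": 35, "b": 15}, {"a": 15, "b": 35}
        s1 = div.AlleleFrequencySpectrum("L", "p1", c1)
        s2 = div.AlleleFrequencySpectrum("L", "p2", c2)
        assert diff.jost_dest([s1, s2]) == pytest.approx(
            oracle_jost(c1, c2), abs=1e-12
        )

    def test_multilocus_harmonic_mean(self):
        assert diff.jost_dest_multilocus([0.2, 0.4]) == pytest.approx(
            2 / (1 / 0.2 + 1 / 0.4)
        )
        with pytest.warns(UserWarning):
            v = diff.jost_dest_multilocus([0.5, -0.1])
        assert 0 < v < 0.5


# -- F' ----------------------------------------------------------------------

class TestFPrime:
    def test_undifferentiated_configuration_zero(self):
        # mean within similarity (0 and 1, averaged) equals mean between (0.5)
        table, pm = make_diploid_table(
            {"p1": [("a", "a"), ("b", "b")], "p2": [("a", "b"), ("a", "b")]}
        )
        res = diff.f_prime(table, pm, "L")
        assert res.s_within == pytest.approx(res.s_between)
        assert res.f_prime == pytest.approx(0.0, abs=1e-12)

    def test_full_differentiation(self):
        table, pm = make_diploid_table(
            {"p1": [("a", "a")] * 3, "p2": [("b", "b")] * 3}
        )
        res = diff.f_prime(table, pm, "L")
        assert res.f_prime == pytest.approx(1.0)
        assert res.s_within == 1.0 and res.s_between == 0.0

    def test_shares_kernel_with_apd(self):
        # 100*(1 - mean within similarity) reproduces apd() per population
        table, pm = make_diploid_table(
            {"p1": [("a", "b"), ("a", "a"), ("b", "c")],
             "p2": [("c", "c"), ("a", "c"), ("b", "b")]}
        )
        within, _, _ = diff._similarity_arrays(table, pm, "L")
        for pop, w in zip(("p1", "p2"), within):
            row = div.apd(table, pm, "L", pop)
            assert 100.0 * (1.0 - w.mean()) == pytest.approx(row.apd, abs=1e-12)

    def test_d_and_fprime_one_iff_disjoint_monomorphic(self):
        table, pm = make_diploid_table(
            {"p1": [("a", "a")] * 4, "p2": [("b", "b")] * 4}
        )
        s1 = div.AlleleFrequencySpectrum("L", "p1", {"a": 8})
        s2 = div.AlleleFrequencySpectrum("L", "p2", {"b": 8})
        assert diff.jost_dest([s1, s2]) == pytest.approx(1.0)
        assert diff.f_prime(table, pm, "L").f_prime == pytest.approx(1.0)
        # shared allele breaks the equality
        table2, pm2 = make_diploid_table(
            {"p1": [("a", "a")] * 4, "p2": [("b", "b")] * 3 + [("a", "a")]}
        )
        assert diff.f_prime(table2, pm2, "L").f_prime < 1.0


# -- exact test --------------------------------------------------------------

class TestExactTest:
    def test_identical_high_probability_table(self, rng):
        tab = np.array([[20, 20], [20, 20]])
        p = diff.exact_test_differentiation(tab, mc_steps=20000, dememorization=2000, rng=rng)
        assert p > 0.8

    def test_2x2_matches_fisher(self, rng):
        tab = np.array([[12, 3], [5, 10]])
        _, p_fisher = fisher_exact(tab)
        p_mc = diff.exact_test_differentiation(
            tab, mc_steps=100000, dememorization=10000, rng=rng
        )
        assert p_mc == pytest.approx(p_fisher, abs=0.01)

    def test_disjoint_alleles_tiny_p(self, rng):
        tab = np.array([[30, 0], [0, 30]])
        p = diff.exact_test_differentiation(tab, mc_steps=50000, dememorization=5000, rng=rng)
        assert p < 0.001

    def test_zero_margin_warns(self, rng):
        with pytest.warns(UserWarning):
            p = diff.exact_test_differentiation(np.array([[0, 0], [5, 5]]), rng=rng)
        assert p == 1.0


def test_panmictic_null_estimators_centred_at_zero(rng):
    """Random splits of one panmictic pool: Phi_ST, D_est and F' all have
    empirical mean within +-0.01 of zero (200 replicates)."""
    from zebramhc._coalescent import sim_infinite_sites
    from zebramhc.io import GenotypeTable, PopulationMap

    # moderate diversity: at very high theta the D_est denominator 1 - H_S
    # approaches zero and the ratio becomes heavy-tailed
    phis, dests, fps = [], [], []
    for _ in range(300):
        hap = sim_infinite_sites(60, 2.0, rng)
        _, inv = np.unique(hap, axis=0, return_inverse=True)
        if len(set(inv)) < 2:
            continue
        names = [f"i{j}" for j in range(30)]
        order = rng.permutation(30)
        assign = {names[j]: ("p1" if k < 15 else "p2") for k, j in enumerate(order)}
        table = GenotypeTable(individuals=names, loci={"L": "sequence_diploid"})
        for j in range(30):
            table.calls[(names[j], "L")] = tuple(
                sorted((f"a{inv[2 * j]}", f"a{inv[2 * j + 1]}"))
            )
        pm = PopulationMap(assign)
        phis.append(
            diff.phi_st_amova(None, table, pm, "L", distance="identity", n_perm=0).phi_st
        )
        spectra = [div.allele_frequencies(table, pm, "L", p) for p in ("p1", "p2")]
        try:
            dests.append(diff.jost_dest(spectra))
        except Exception:
            pass
        fps.append(diff.f_prime(table, pm, "L", jackknife=False).f_prime)
    assert abs(np.mean(phis)) < 0.01
    assert abs(np.mean(dests)) < 0.01
    assert abs(np.mean(fps)) < 0.01


def test_distance_matrix_export_round_trip(tmp_path):
    import pandas as pd

    aln = LocusAlignment("t", ["u", "v"], ["AAAA", "AAAG"])
    path = tmp_path / "d.tsv"
    diff.export_distance_matrix(aln, path, distance="k2p")
    back = pd.read_csv(path, sep="\t", index_col=0)
    assert back.shape == (2, 2)
    assert back.loc["u", "v"] == pytest.approx(
        diff.k2p_distance("AAAA", "AAAG"), abs=1e-9
    )
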