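"""Synthetic-data generators: determinism, calibration, and designed contrasts.

Replicate counts and deme sizes here are desk-scale choices; the statistical
expectations they check (island-model F_ST, neutral Tajima's D, binomial
detection thinning, closed-form PCR-error rates) are independent of the scale.
"""

import io

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

from zebramhc import differentiation as diff
from zebramhc import diversity as div
from zebramhc import mismatch as mm
from zebramhc import neutrality as neut
from zebramhc.errors import ParameterError
from zebramhc.io import GenotypeTable
from zebramhc.simulate import (
    SeqLocusSpec,
    SimScenario,
    generate_pcr_replicates,
    simulate_balancing_locus,
    simulate_expansion,
    simulate_msat_two_pop,
    simulate_multicopy_genotypes,
    simulate_seq_two_pop,
)


def fasta_bytes(aln):
    buf = io.StringIO()
    for a, s in zip(aln.allele_ids, aln.sequences):
        buf.write(f">{a}\n{s}\n")
    return buf.getvalue()


class TestDeterminism:
    def test_msat_run_twice_identical(self):
        sc = SimScenario(seed=1, n_individuals=(10, 10), n_msat_loci=3, deme_size=60)
        t1, _ = simulate_msat_two_pop(sc)
        t2, _ = simulate_msat_two_pop(
            SimScenario(seed=1, n_individuals=(10, 10), n_msat_loci=3, deme_size=60)
        )
        assert t1.calls == t2.calls

    def test_seq_fasta_bytes_identical(self):
        sc = SimScenario(seed=4, n_individuals=(8, 8), deme_size=100)
        spec = SeqLocusSpec("x", 300, theta=3.0)
        a1, _, _ = simulate_seq_two_pop(sc, spec)
        a2, _, _ = simulate_seq_two_pop(
            SimScenario(seed=4, n_individuals=(8, 8), deme_size=100), spec
        )
        assert fasta_bytes(a1) == fasta_bytes(a2)

    def test_expansion_bytes_identical(self):
        a1 = simulate_expansion(SimScenario(seed=9, expansion_n=20))
        a2 = simulate_expansion(SimScenario(seed=9, expansion_n=20))
        assert fasta_bytes(a1) == fasta_bytes(a2)


class TestMsatIslandModel:
    def test_high_migration_low_fst_and_monotonicity(self):
        """m=0.5 keeps multilocus theta below 0.02; m=0 exceeds it, pairwise."""
        low, ordered = 0, 0
        reps = 50
        for i in range(reps):
            base = dict(n_individuals=(25, 25), n_msat_loci=5, deme_size=500)
            t_hi, pm_hi = simulate_msat_two_pop(SimScenario(seed=300 + i, migration_rate=0.5, **base))
            t_no, pm_no = simulate_msat_two_pop(SimScenario(seed=300 + i, migration_rate=0.0, **base))
            th_hi = diff.wc_fst(t_hi, pm_hi, n_boot=0).multilocus
            th_no = diff.wc_fst(t_no, pm_no, n_boot=0).multilocus
            low += th_hi < 0.02
            ordered += th_no > th_hi
        assert low >= int(0.95 * reps)
        assert ordered >= int(0.95 * reps)


class TestSeqTwoPop:
    def test_theta_zero_monomorphic(self):
        sc = SimScenario(seed=2, n_individuals=(10, 10), deme_size=100)
        aln, table, _ = simulate_seq_two_pop(sc, SeqLocusSpec("z", 100, theta=0.0))
        assert len(aln.allele_ids) == 1

    def test_capacity_error(self):
        sc = SimScenario(seed=3, n_individuals=(30, 30), deme_size=500)
        with pytest.raises(Exception):
            simulate_seq_two_pop(sc, SeqLocusSpec("z", 3, theta=50.0))

    def test_single_deme_neutral_tajima_calibration(self):
        """Mean Tajima's D across 1000 neutral single-deme samples within +-0.15 of 0."""
        ds = []
        for i in range(1000):
            sc = SimScenario(seed=5000 + i, n_individuals=(15, 15), deme_size=1000)
            aln, table, pm = simulate_seq_two_pop(
                sc, SeqLocusSpec("n", 500, theta=5.0), n_demes=1
            )
            copies = div.gene_copies(table, pm, "n", "pop1")
            st = div.seq_diversity_stats(aln, copies)
            if st.S >= 1:
                ds.append(neut.tajimas_d(st.S, st.k, len(copies)))
        assert abs(np.mean(ds)) < 0.15


class TestBalancingLocus:
    def test_s_zero_matches_neutral_mode(self):
        """s=0 overdominance is plain drift: homozygosity distributions agree."""
        f_null, f_zero = [], []
        for i in range(60):
            base = dict(n_individuals=(15, 15), deme_size=100)
            for mode, sink in (("neutral", f_null), ("overdominant", f_zero)):
                spec = SeqLocusSpec("b", 200, theta=2.0, selection=mode, s=0.0)
                _, gt, pm = simulate_balancing_locus(
                    SimScenario(seed=7000 + i, **base), spec
                )
                spec_f = div.allele_frequencies(gt, pm, "b", "pop1")
                f = sum(v**2 for v in spec_f.frequencies.values())
                sink.append(f)
        _, p = kstest(f_null, f_zero)
        assert p > 0.01

    def test_overdominance_reduces_fst(self):
        """Selected locus shows lower F_ST than a paired neutral locus."""
        wins = 0
        reps = 15
        for i in range(reps):
            base = dict(n_individuals=(25, 25), deme_size=150)
            sel = SeqLocusSpec("s", 200, theta=2.0, selection="overdominant", s=0.3)
            neu = SeqLocusSpec("s", 200, theta=2.0, selection="neutral")
            _, gt_s, pm_s = simulate_balancing_locus(SimScenario(seed=8000 + i, **base), sel)
            _, gt_n, pm_n = simulate_balancing_locus(SimScenario(seed=8000 + i, **base), neu)
            fst_s = diff.haplotype_fst_from_spectra(
                [div.allele_frequencies(gt_s, pm_s, "s", p) for p in ("pop1", "pop2")]
            )
            fst_n = diff.haplotype_fst_from_spectra(
                [div.allele_frequencies(gt_n, pm_n, "s", p) for p in ("pop1", "pop2")]
            )
            wins += fst_s < fst_n
        assert wins >= int(0.6 * reps)

    def test_skewed_mode_hits_target(self):
        spec = SeqLocusSpec("d", 246, theta=2.0, selection="skewed", skew_target=0.44)
        sc = SimScenario(seed=11, n_individuals=(36, 31), deme_size=200)
        _, gt, pm = simulate_balancing_locus(sc, spec)
        freqs = div.allele_frequencies(gt, pm, "d", "pop1").frequencies
        assert max(freqs.values()) == pytest.approx(0.44, abs=0.05)

    def test_invalid_s_rejected(self):
        spec = SeqLocusSpec("d", 100, theta=1.0, selection="overdominant", s=1.5)
        with pytest.raises(ParameterError):
            SimScenario(seed=1, seq_loci=(spec,))


def _fully_het_base(n):
    """Base table: every individual carries 4 distinct alleles over 2 loci."""
    loci = {"c1": "sequence_diploid", "c2": "sequence_diploid"}
    t = GenotypeTable(individuals=[f"i{j}" for j in range(n)], loci=loci)
    for j in range(n):
        t.calls[(f"i{j}", "c1")] = (f"a{j}", f"b{j}")
        t.calls[(f"i{j}", "c2")] = (f"c{j}", f"d{j}")
    return t


class TestMulticopy:
    def test_no_dropout_keeps_four_alleles(self, rng):
        sc = SimScenario(seed=1, detection_dropout=0.0)
        out = simulate_multicopy_genotypes(sc, _fully_het_base(20), rng=rng)
        assert all(len(out.call(i, "dqa")) == 4 for i in out.individuals)

    def test_full_dropout_all_missing(self, rng):
        sc = SimScenario(seed=1, detection_dropout=1.0)
        out = simulate_multicopy_genotypes(sc, _fully_het_base(20), rng=rng)
        assert all(out.call(i, "dqa") is None for i in out.individuals)

    def test_binomial_thinning_distribution(self, rng):
        sc = SimScenario(seed=1, detection_dropout=0.3)
        out = simulate_multicopy_genotypes(sc, _fully_het_base(2000), rng=rng)
        observed = np.bincount(
            [len(out.call(i, "dqa") or ()) for i in out.individuals], minlength=5
        )
        from scipy.stats import binom

        expected = binom.pmf(np.arange(5), 4, 0.7) * 2000
        _, p = chisquare(observed, expected)
        assert p > 0.01


class TestPcrReplicates:
    def _truth(self, n_het, n_hom=0):
        t = GenotypeTable(
            individuals=[f"i{j}" for j in range(n_het + n_hom)],
            loci={"L": "microsatellite"},
        )
        for j in range(n_het):
            t.calls[(f"i{j}", "L")] = ("A", "B")
        for j in range(n_het, n_het + n_hom):
            t.calls[(f"i{j}", "L")] = ("A", "A")
        return t

    def test_error_free_replicates_identical(self, rng):
        truth = self._truth(30, 10)
        reps = generate_pcr_replicates(truth, 0.0, 0.0, 3, rng=rng)
        assert all(r.calls == truth.calls for r in reps)

    def test_full_dropout_heterozygotes_become_homozygotes(self, rng):
        truth = self._truth(40)
        (rep,) = generate_pcr_replicates(truth, 1.0, 0.0, 1, rng=rng)
        assert all(rep.call(i, "L")[0] == rep.call(i, "L")[1] for i in truth.individuals)

    def test_hom_miscall_rate_closed_form(self, rng):
        # P(>=1 allele drops) = 2*0.2*0.8 + 0.2^2 = 0.36
        truth = self._truth(10000)
        (rep,) = generate_pcr_replicates(truth, 0.2, 0.0, 1, rng=rng)
        miscalls = sum(
            rep.call(i, "L")[0] == rep.call(i, "L")[1] for i in truth.individuals
        )
        assert miscalls / 10000 == pytest.approx(0.36, abs=0.02)


class TestExpansion:
    def test_constant_size_mean_pairwise_equals_theta(self):
        ks = []
        for i in range(200):
            sc = SimScenario(
                seed=100 + i, expansion_tau=0.0, expansion_theta0=3.0,
                expansion_theta1=3.0, expansion_n=30,
            )
            aln = simulate_expansion(sc)
            hist = mm.mismatch_histogram(aln, aln.allele_ids)
            ks.append(float(np.sum(np.arange(len(hist)) * hist)))
        assert np.mean(ks) == pytest.approx(3.0, rel=0.15)

    def test_strong_expansion_mode_near_tau(self):
        hits = reps = 0
        for i in range(30):
            sc = SimScenario(
                seed=400 + i, expansion_tau=5.0, expansion_theta0=1.0,
                expansion_theta1=1000.0, expansion_n=50,
            )
            aln = simulate_expansion(sc)
            hist = mm.mismatch_histogram(aln, aln.allele_ids)
            reps += 1
            hits += 3 <= int(np.argmax(hist)) <= 7
        assert hits >= int(0.8 * reps)

    def test_negative_tau_rejected(self):
        with pytest.raises(ParameterError):
            simulate_expansion(SimScenario(seed=1, expansion_tau=-1.0))
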