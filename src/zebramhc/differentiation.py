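"""Between-population divergence statistics.

Variance-based: Weir–Cockerham theta for codominant diploid loci and AMOVA
Phi_ST for sequence loci (Kimura two-parameter or haplotype-identity
distances); frequency-based: Jost's D_est with Nei–Chesser nearly unbiased
gene-diversity estimators; similarity-based: F', the F_ST analog built from
mean pairwise Dice similarity within vs between populations (the same kernel
as APD); and the Raymond–Rousset Markov-chain exact test of differentiation.

Permutation tests move whole individuals (both gene copies together), which is
conservative under within-individual correlation.  All permutation/MC p-values
use the add-one convention (1 + #extreme)/(reps + 1).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .diversity import AlleleFrequencySpectrum, allele_multiset, dice_similarity
from .errors import DataError, ParameterError, UndefinedStatisticError
from .io import GenotypeTable, LocusAlignment, PopulationMap

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


# -- Weir & Cockerham theta --------------------------------------------------

def _wc_components_locus(pop_calls: list[list[tuple]]) -> tuple[float, float, float]:
    """Summed variance components (a, b, c) over alleles for one locus.

    ``pop_calls``: per population, the list of full diploid calls (half-locus
    and missing calls must already be excluded).
    """
    r = len(pop_calls)
    n_i = np.array([len(c) for c in pop_calls], dtype=float)
    if np.any(n_i < 1) or r < 2:
        raise ParameterError("need >= 2 populations with >= 1 full genotype")
    alleles = sorted({a for calls in pop_calls for call in calls for a in call})
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0  # monomorphic: zero components
    nbar = n_i.mean()
    rn = r * nbar
    nc = (rn - np.sum(n_i**2) / rn) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array(
            [sum(call.count(allele) for call in calls) / (2 * len(calls)) for calls in pop_calls]
        )
        h_i = np.array(
            [
                sum(1 for call in calls if (allele in call) and call[0] != call[1]) / len(calls)
                for calls in pop_calls
            ]
        )
        pbar = float(np.sum(n_i * p_i) / rn)
        s2 = float(np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(n_i * h_i) / rn)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


@dataclass
class WCFstResult:
    per_locus: dict[str, float]
    multilocus: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_per_locus: dict[str, float]
    p_multilocus: Optional[float]


def _full_calls_by_pop(
    table: GenotypeTable, popmap: PopulationMap, locus: str, members_by_pop: dict[str, list[str]]
) -> list[list[tuple]]:
    out = []
    for pop, members in members_by_pop.items():
        calls = []
        for ind in members:
            call = table.call(ind, locus)
            if call is not None and call[1] is not None:
                calls.append(call)
        out.append(calls)
    return out


def wc_fst(
    table: GenotypeTable,
    popmap: PopulationMap,
    loci: Optional[Sequence[str]] = None,
    n_boot: int = 10000,
    n_perm: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> WCFstResult:
    """Weir–Cockerham (1984) theta per locus and multilocus, with a bootstrap
    CI over loci and optional permutation p-values (individuals shuffled among
    populations)."""
    rng = np.random.default_rng() if rng is None else rng
    if loci is None:
        loci = [l for l, k in table.loci.items() if k != "sequence_multicopy"]
    members_by_pop = {p: popmap.members(p) for p in popmap.population_names}
    if len(members_by_pop) < 2:
        raise ParameterError("need >= 2 populations")

    comps = {}
    for locus in loci:
        pop_calls = _full_calls_by_pop(table, popmap, locus, members_by_pop)
        if min(len(c) for c in pop_calls) < 1:
            warnings.warn(f"{locus}: a population has no full genotypes; skipped")
            continue
        comps[locus] = _wc_components_locus(pop_calls)
    per_locus = {}
    kept = []
    for locus, (a, b, c) in comps.items():
        tot = a + b + c
        if tot == 0.0:
            warnings.warn(f"{locus}: monomorphic, excluded from multilocus theta")
            per_locus[locus] = float("nan")
        else:
            per_locus[locus] = a / tot
            kept.append(locus)
    if not kept:
        raise DataError("no polymorphic loci")
    a_arr = np.array([comps[l][0] for l in kept])
    tot_arr = np.array([sum(comps[l]) for l in kept])
    multilocus = float(a_arr.sum() / tot_arr.sum())

    ci_low = ci_high = None
    if n_boot > 0 and len(kept) > 1:
        idx = rng.integers(0, len(kept), size=(n_boot, len(kept)))
        boots = a_arr[idx].sum(axis=1) / tot_arr[idx].sum(axis=1)
        ci_low, ci_high = (float(x) for x in np.percentile(boots, [2.5, 97.5]))

    p_per_locus: dict[str, float] = {}
    p_multi = None
    if n_perm > 0:
        inds = [i for p in members_by_pop.values() for i in p]
        sizes = [len(m) for m in members_by_pop.values()]
        count_multi = 0
        counts_locus = {l: 0 for l in kept}
        for _ in range(n_perm):
            perm = list(rng.permutation(inds))
            perm_members: dict[str, list[str]] = {}
            start = 0
            for pop, size in zip(members_by_pop, sizes):
                perm_members[pop] = perm[start:start + size]
                start += size
            a_tot = t_tot = 0.0
            for locus in kept:
                pop_calls = _full_calls_by_pop(table, popmap, locus, perm_members)
                if min(len(c) for c in pop_calls) < 1:
                    continue
                a, b, c = _wc_components_locus(pop_calls)
                if a + b + c != 0:
                    if a / (a + b + c) >= per_locus[locus] - 1e-12:
                        counts_locus[locus] += 1
                a_tot += a
                t_tot += a + b + c
            if t_tot > 0 and a_tot / t_tot >= multilocus - 1e-12:
                count_multi += 1
        p_per_locus = {l: (1 + c) / (n_perm + 1) for l, c in counts_locus.items()}
        p_multi = (1 + count_multi) / (n_perm + 1)
    return WCFstResult(
        per_locus=per_locus, multilocus=multilocus, ci_low=ci_low, ci_high=ci_high,
        p_per_locus=p_per_locus, p_multilocus=p_multi,
    )


# -- K2P distance ------------------------------------------------------------

def k2p_distance(seq1: str, seq2: str, skip_columns: frozenset[int] = frozenset()) -> float:
    """Kimura two-parameter distance; gap/ambiguous sites excluded pairwise.

    Returns ``inf`` (with a warning) at saturation, where a log argument
    reaches zero or below.
    """
    if len(seq1) != len(seq2):
        raise ParameterError("sequences must have equal length")
    valid = transitions = transversions = 0
    for i, (x, y) in enumerate(zip(seq1, seq2)):
        if i in skip_columns or x not in "ACGT" or y not in "ACGT":
            continue
        valid += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    if valid == 0:
        raise ParameterError("no comparable sites")
    P = transitions / valid
    Q = transversions / valid
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        warnings.warn("K2P saturation: distance set to inf")
        return math.inf
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


# -- AMOVA Phi_ST ------------------------------------------------------------

@dataclass
class AmovaResult:
    phi_st: float
    sigma2_a: float
    sigma2_w: float
    p: Optional[float]


def _amova_from_counts(count_mat: np.ndarray, d2: np.ndarray) -> tuple[float, float, float]:
    """AMOVA variance components from per-population allele-count vectors.

    ``count_mat``: (P, A) gene-copy counts per population over A distinct
    alleles; ``d2``: (A, A) squared distances between alleles.
    """
    n_p = count_mat.sum(axis=1).astype(float)
    keep = n_p >= 2
    count_mat = count_mat[keep]
    n_p = n_p[keep]
    P = count_mat.shape[0]
    if P < 2:
        raise ParameterError("need >= 2 populations with >= 2 gene copies")
    N = float(n_p.sum())
    total = count_mat.sum(axis=0).astype(float)
    ss_t = float(total @ d2 @ total) / (2.0 * N)
    ss_w = float(sum((c @ d2 @ c) / (2.0 * n) for c, n in zip(count_mat, n_p)))
    df_w = N - P
    df_a = P - 1
    sigma2_w = ss_w / df_w
    ms_a = (ss_t - ss_w) / df_a
    n_prime = (N - float(np.sum(n_p**2)) / N) / df_a
    sigma2_a = (ms_a - sigma2_w) / n_prime
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom != 0 else 0.0
    return phi, sigma2_a, sigma2_w


def phi_st_amova(
    aln: Optional[LocusAlignment],
    table: GenotypeTable,
    popmap: PopulationMap,
    locus: str,
    distance: str = "k2p",
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> AmovaResult:
    """Two-level AMOVA Phi_ST among populations for a sequence locus.

    ``distance='k2p'`` uses Kimura two-parameter distances between haplotypes
    (treated as squared distances, Arlequin-style); ``'identity'`` uses the 0/1
    haplotype-identity distance, which yields the conventional haplotype F_ST.
    The permutation null shuffles individuals among populations.
    """
    rng = np.random.default_rng() if rng is None else rng
    if distance not in ("k2p", "identity"):
        raise ParameterError(f"unknown distance {distance!r}")
    pops = popmap.population_names
    # per-individual allele count vectors
    ind_alleles: list[tuple[str, list[str]]] = []
    for ind in table.individuals:
        alleles = list(table.alleles_of(ind, locus))
        if alleles:
            ind_alleles.append((popmap.population_of(ind), alleles))
    uniq = sorted({a for _, alleles in ind_alleles for a in alleles})
    aidx = {a: i for i, a in enumerate(uniq)}
    A = len(uniq)
    d2 = np.zeros((A, A))
    if distance == "identity":
        d2 = 1.0 - np.eye(A)
    else:
        if aln is None:
            raise ParameterError("K2P distance requires an alignment")
        skip = aln.indel_columns
        for i in range(A):
            for j in range(i + 1, A):
                d = k2p_distance(aln.sequence(uniq[i]), aln.sequence(uniq[j]), skip)
                if not math.isfinite(d):
                    raise DataError("saturated K2P distance in AMOVA")
                d2[i, j] = d2[j, i] = d
    ind_vecs = np.zeros((len(ind_alleles), A))
    pop_labels = np.array([pops.index(p) for p, _ in ind_alleles])
    for row, (_, alleles) in enumerate(ind_alleles):
        for a in alleles:
            ind_vecs[row, aidx[a]] += 1

    def counts_for(labels: np.ndarray) -> np.ndarray:
        return np.stack([ind_vecs[labels == p].sum(axis=0) for p in range(len(pops))])

    phi, s2a, s2w = _amova_from_counts(counts_for(pop_labels), d2)
    p = None
    if n_perm > 0:
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pop_labels)
            try:
                phi_p, _, _ = _amova_from_counts(counts_for(perm), d2)
            except ParameterError:
                continue
            count += phi_p >= phi - 1e-12
        p = (1 + count) / (n_perm + 1)
    return AmovaResult(phi_st=float(phi), sigma2_a=float(s2a), sigma2_w=float(s2w), p=p)


def haplotype_fst_from_spectra(spectra: Sequence[AlleleFrequencySpectrum]) -> float:
    """Conventional haplotype F_ST: AMOVA with the identity distance computed
    directly from allele spectra."""
    alleles = sorted({a for s in spectra for a in s.counts})
    counts = np.array([[s.counts.get(a, 0) for a in alleles] for s in spectra], dtype=float)
    d2 = 1.0 - np.eye(len(alleles))
    phi, _, _ = _amova_from_counts(counts, d2)
    return float(phi)


# -- Jost's D ----------------------------------------------------------------

def jost_dest(spectra: Sequence[AlleleFrequencySpectrum]) -> float:
    """Jost's D_est from per-population spectra, with Nei–Chesser nearly
    unbiased H_S and H_T estimators (gene-copy sample sizes)."""
    P = len(spectra)
    if P < 2:
        raise ParameterError("need >= 2 populations")
    n_p = np.array([s.n for s in spectra], dtype=float)
    if np.any(n_p < 2):
        raise ParameterError("need >= 2 gene copies per population")
    alleles = sorted({a for s in spectra for a in s.counts})
    freqs = np.array([[s.frequencies.get(a, 0.0) for a in alleles] for s in spectra])
    n_harm = P / np.sum(1.0 / n_p)
    hs_plug = 1.0 - float(np.mean(np.sum(freqs**2, axis=1)))
    hs = (n_harm / (n_harm - 1.0)) * hs_plug
    pbar = freqs.mean(axis=0)
    ht_plug = 1.0 - float(np.sum(pbar**2))
    ht = ht_plug + hs / (n_harm * P)
    if hs >= 1.0:
        raise UndefinedStatisticError("H_S = 1: D_est undefined")
    return float((P / (P - 1.0)) * (ht - hs) / (1.0 - hs))


def jost_dest_multilocus(values: Sequence[float], floor: float = 1e-6) -> float:
    """Harmonic mean of per-locus D_est; non-positive values floored (flagged)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ParameterError("no per-locus values")
    if np.any(vals <= 0):
        warnings.warn("non-positive D_est floored inside harmonic mean")
        vals = np.maximum(vals, floor)
    return float(vals.size / np.sum(1.0 / vals))


# -- F' (similarity-based differentiation) -----------------------------------

@dataclass
class FPrimeResult:
    f_prime: float
    se_delta: float
    se_jackknife: float
    s_within: float
    s_between: float


def _similarity_arrays(
    table: GenotypeTable, popmap: PopulationMap, locus: str
) -> tuple[list[np.ndarray], np.ndarray, list[list[Counter]]]:
    pops = popmap.population_names
    multisets: list[list[Counter]] = []
    for pop in pops:
        ms = [allele_multiset(table, i, locus) for i in popmap.members(pop)]
        multisets.append([m for m in ms if m])
    within = []
    for ms in multisets:
        vals = [
            dice_similarity(ms[i], ms[j])
            for i in range(len(ms))
            for j in range(i + 1, len(ms))
        ]
        within.append(np.array(vals))
    between = np.array(
        [
            dice_similarity(x, y)
            for pi in range(len(pops))
            for pj in range(pi + 1, len(pops))
            for x in multisets[pi]
            for y in multisets[pj]
        ]
    )
    return within, between, multisets


def f_prime(
    table: GenotypeTable,
    popmap: PopulationMap,
    locus: str,
    jackknife: bool = True,
) -> FPrimeResult:
    """F' = (S_w - S_b) / (1 - S_b): mean within- vs between-population pairwise
    Dice similarity.  S_w is the unweighted mean of the per-population means.
    SEs: delta-method propagation treating pairs as independent, and a
    jackknife over individuals."""
    within, between, multisets = _similarity_arrays(table, popmap, locus)
    if any(len(w) < 1 for w in within) or len(between) < 1:
        raise ParameterError("need >= 2 individuals per population")
    s_w = float(np.mean([w.mean() for w in within]))
    s_b = float(between.mean())
    if s_b >= 1.0:
        raise UndefinedStatisticError("between-population similarity = 1: F' undefined")
    fp = (s_w - s_b) / (1.0 - s_b)
    # delta method
    var_sw = sum(np.var(w, ddof=1) / len(w) for w in within) / len(within) ** 2
    var_sb = float(np.var(between, ddof=1) / len(between))
    d_sw = 1.0 / (1.0 - s_b)
    d_sb = (s_w - 1.0) / (1.0 - s_b) ** 2
    se_delta = math.sqrt(d_sw**2 * var_sw + d_sb**2 * var_sb)
    if not jackknife:
        return FPrimeResult(
            f_prime=float(fp), se_delta=float(se_delta), se_jackknife=float("nan"),
            s_within=s_w, s_between=s_b,
        )
    # jackknife over individuals
    pseudo = []
    for pi, ms in enumerate(multisets):
        for drop in range(len(ms)):
            reduced = [
                [m for k, m in enumerate(mm) if not (pj == pi and k == drop)]
                for pj, mm in enumerate(multisets)
            ]
            sw_parts = []
            ok = True
            for mm in reduced:
                vals = [
                    dice_similarity(mm[i], mm[j])
                    for i in range(len(mm))
                    for j in range(i + 1, len(mm))
                ]
                if not vals:
                    ok = False
                    break
                sw_parts.append(np.mean(vals))
            if not ok:
                continue
            bvals = [
                dice_similarity(x, y)
                for a in range(len(reduced))
                for b in range(a + 1, len(reduced))
                for x in reduced[a]
                for y in reduced[b]
            ]
            sbj = np.mean(bvals)
            if sbj >= 1.0:
                continue
            pseudo.append((np.mean(sw_parts) - sbj) / (1.0 - sbj))
    pseudo_arr = np.array(pseudo)
    J = len(pseudo_arr)
    se_jack = (
        math.sqrt((J - 1) / J * float(np.sum((pseudo_arr - pseudo_arr.mean()) ** 2)))
        if J > 1
        else float("nan")
    )
    return FPrimeResult(
        f_prime=float(fp), se_delta=float(se_delta), se_jackknife=float(se_jack),
        s_within=s_w, s_between=s_b,
    )


# -- exact test of differentiation -------------------------------------------

def _log_table_prob_kernel(table: np.ndarray) -> float:
    """-sum log(n_ij!): the margin-conditional table probability up to constants."""
    return -float(np.sum(gammaln(table + 1.0)))


def exact_test_differentiation(
    counts: np.ndarray,
    mc_steps: int = 100000,
    dememorization: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Raymond–Rousset Markov-chain exact test on an R-alleles x P-populations
    count table; p estimates the probability mass of margin-fixed tables no
    more probable than the observed one."""
    rng = np.random.default_rng() if rng is None else rng
    tab = np.asarray(counts, dtype=int).copy()
    if tab.ndim != 2:
        raise ParameterError("counts must be 2-D")
    if np.any(tab.sum(axis=1) == 0) or np.any(tab.sum(axis=0) == 0):
        warnings.warn("zero margin: exact test p = 1")
        return 1.0
    R, C = tab.shape
    if R < 2 or C < 2:
        warnings.warn("degenerate table: exact test p = 1")
        return 1.0
    log_obs = _log_table_prob_kernel(tab)
    log_cur = log_obs
    hits = 0
    rows = rng.integers(0, R, size=(dememorization + mc_steps, 2))
    cols = rng.integers(0, C, size=(dememorization + mc_steps, 2))
    us = rng.random(dememorization + mc_steps)
    for step in range(dememorization + mc_steps):
        r1, r2 = rows[step]
        c1, c2 = cols[step]
        if r1 != r2 and c1 != c2:
            n11, n22 = tab[r1, c1], tab[r2, c2]
            n12, n21 = tab[r1, c2], tab[r2, c1]
            if n11 > 0 and n22 > 0:
                ratio = (n11 * n22) / ((n12 + 1) * (n21 + 1))
                if us[step] < ratio:
                    tab[r1, c1] -= 1
                    tab[r2, c2] -= 1
                    tab[r1, c2] += 1
                    tab[r2, c1] += 1
                    log_cur += (
                        math.log(n11) + math.log(n22)
                        - math.log(n12 + 1) - math.log(n21 + 1)
                    )
        if step >= dememorization and log_cur <= log_obs + 1e-9:
            hits += 1
    return hits / mc_steps


def export_distance_matrix(
    aln: LocusAlignment, path, distance: str = "k2p"
) -> None:
    """Write the square inter-haplotype distance matrix as TSV."""
    import pandas as pd

    ids = aln.allele_ids
    n = len(ids)
    mat = np.zeros((n, n))
    skip = aln.indel_columns
    for i in range(n):
        for j in range(i + 1, n):
            if distance == "k2p":
                d = k2p_distance(aln.sequences[i], aln.sequences[j], skip)
            elif distance == "identity":
                d = float(aln.sequences[i] != aln.sequences[j])
            else:
                raise ParameterError(f"unknown distance {distance!r}")
            mat[i, j] = mat[j, i] = d
    pd.DataFrame(mat, index=ids, columns=ids).to_csv(path, sep="\t")


def fisher_combined_p(p_values: Sequence[float]) -> float:
    """Fisher's combination of independent per-locus exact-test p-values."""
    ps = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
    stat = -2.0 * float(np.sum(np.log(ps)))
    return float(chi2.sf(stat, df=2 * len(ps)))
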