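"""Within-population diversity indices for all marker classes.

Covers allele-frequency spectra (including the count-once convention for the
possibly-duplicated MHC locus), hypergeometric rarefaction of allelic richness,
expected/observed heterozygosity, sequence diversity (S, k, haplotype diversity,
nucleotide diversity with Nei sampling variances) and the APD similarity
statistic (average percent difference between individuals' allele sets).

Allele-frequency conventions
----------------------------
``diploid`` mode counts two gene copies per homozygote and one per allele of a
heterozygote; a half-locus call contributes its scored allele once and one gene
copy to the total.  ``multicopy`` mode implements the count-once rule for loci
of uncertain copy number: an individual showing a single allele contributes two
copies of it, an individual showing >=2 distinct alleles contributes one copy of
each.  This underestimates common-allele and overestimates rare-allele
frequencies, which is why the frequency-free APD statistic is carried alongside.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import DataError, ParameterError
from .io import GenotypeTable, LocusAlignment, PopulationMap


@dataclass
class AlleleFrequencySpectrum:
    locus_id: str
    population: str
    counts: dict[str, int]
    estimation_mode: str = "diploid"  # or "multicopy"

    @property
    def n(self) -> int:
        """Total gene copies counted."""
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.n
        return {a: c / n for a, c in self.counts.items()}

    @property
    def n_alleles(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def count_vector(self) -> np.ndarray:
        return np.array([c for c in self.counts.values() if c > 0], dtype=int)


def allele_frequencies(
    table: GenotypeTable,
    popmap: PopulationMap,
    locus: str,
    population: str,
    mode: str = "diploid",
) -> AlleleFrequencySpectrum:
    """Allele counts and frequencies for one locus in one population."""
    if mode not in ("diploid", "multicopy"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mode == "multicopy" and table.loci[locus] != "sequence_multicopy":
        raise ParameterError("multicopy mode only applies to sequence_multicopy loci")
    members = popmap.members(population)
    if not members:
        raise DataError(f"empty population {population!r}")
    counts: Counter = Counter()
    for ind in members:
        call = table.call(ind, locus)
        if call is None:
            continue
        if mode == "multicopy":
            alleles = [a for a in call if a is not None]
            if len(alleles) == 1:
                counts[alleles[0]] += 2
            else:
                for a in alleles:
                    counts[a] += 1
        else:
            a, b = call
            if b is None:  # half-locus: scored allele once, one gene copy
                counts[a] += 1
            else:
                counts[a] += 1
                counts[b] += 1
    return AlleleFrequencySpectrum(
        locus_id=locus, population=population, counts=dict(counts), estimation_mode=mode
    )


def allelic_richness_rarefied(spectrum: AlleleFrequencySpectrum, g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    Hypergeometric rarefaction: ``A_g = sum_i [1 - C(n - n_i, g) / C(n, g)]``.
    At ``g = n`` this equals the observed allele count; at ``g = 1`` it equals 1
    for any non-empty sample.
    """
    n = spectrum.n
    if not 1 <= g <= n:
        raise ParameterError(f"rarefaction size g={g} outside [1, n={n}]")
    denom = math.comb(n, g)
    total = 0.0
    for n_i in spectrum.counts.values():
        if n_i <= 0:
            continue
        total += 1.0 - math.comb(n - n_i, g) / denom
    return total


@dataclass
class Heterozygosity:
    h_exp: float
    h_exp_unbiased: float
    h_obs: Optional[float]  # None for multicopy loci (undefined)


def heterozygosity(
    spectrum: AlleleFrequencySpectrum,
    table: Optional[GenotypeTable] = None,
    popmap: Optional[PopulationMap] = None,
) -> Heterozygosity:
    """Expected heterozygosity (plain and n/(n-1)-unbiased) and, when genotypes
    for a diploid locus are supplied, the observed heterozygote fraction."""
    n = spectrum.n
    if n < 2:
        raise ParameterError("need at least 2 gene copies")
    h = 1.0 - sum(f * f for f in spectrum.frequencies.values())
    h_unb = h * n / (n - 1)
    h_obs = None
    if (
        table is not None
        and popmap is not None
        and spectrum.estimation_mode == "diploid"
        and table.loci[spectrum.locus_id] != "sequence_multicopy"
    ):
        het = tot = 0
        for ind in popmap.members(spectrum.population):
            call = table.call(ind, spectrum.locus_id)
            if call is None or call[1] is None:  # half-locus cannot be classified
                continue
            tot += 1
            het += call[0] != call[1]
        h_obs = het / tot if tot else None
    return Heterozygosity(h_exp=h, h_exp_unbiased=h_unb, h_obs=h_obs)


# -- sequence diversity ------------------------------------------------------

@dataclass
class SeqDiversity:
    n: int              # gene copies
    S: int              # segregating (non-indel) sites
    indel_bp: int       # indel columns varying within this sample
    k: float            # mean pairwise differences
    hd: float           # haplotype diversity
    hd_sd: float
    pi: float           # k / analyzed_sites
    pi_sd: float
    analyzed_sites: int


def pairwise_differences(aln: LocusAlignment, id_a: str, id_b: str) -> int:
    """Nucleotide differences between two haplotypes over non-indel columns."""
    sa, sb = aln.sequence(id_a), aln.sequence(id_b)
    skip = aln.indel_columns
    return sum(1 for i, (x, y) in enumerate(zip(sa, sb)) if i not in skip and x != y)


def difference_matrix(aln: LocusAlignment, allele_ids: Sequence[str]) -> np.ndarray:
    """Pairwise substitution-difference matrix over non-indel columns
    (vectorized byte comparison)."""
    mat = np.frombuffer(
        "".join(aln.sequence(a) for a in allele_ids).encode(), dtype=np.uint8
    ).reshape(len(allele_ids), aln.alignment_length)
    if aln.indel_columns:
        keep = np.ones(aln.alignment_length, dtype=bool)
        keep[list(aln.indel_columns)] = False
        mat = mat[:, keep]
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2)


def gene_copies(
    table: GenotypeTable, popmap: PopulationMap, locus: str, population: str
) -> list[str]:
    """The sampled gene copies (allele IDs with multiplicity) for a diploid
    sequence locus in one population.  Half-locus calls contribute one copy."""
    copies: list[str] = []
    for ind in popmap.members(population):
        call = table.call(ind, locus)
        if call is None:
            continue
        for a in call:
            if a is not None:
                copies.append(a)
    return copies


def seq_diversity_stats(aln: LocusAlignment, copies: Sequence[str]) -> SeqDiversity:
    """S, indel bp, k, haplotype diversity and nucleotide diversity for one
    population sample of gene copies.

    Haplotype identity incorporates indel state (distinct gap patterns are
    distinct alleles); S, k and pi use complete deletion of indel columns.
    Sampling variances follow Nei (1987): eq. 8.12 for haplotype diversity and
    eq. 10.7 for nucleotide diversity.
    """
    n = len(copies)
    if n < 2:
        raise ParameterError("need >= 2 gene copies")
    hap_counts = Counter(copies)
    uniq = list(hap_counts)
    skip = aln.indel_columns
    L = aln.analyzed_sites
    if L < 1:
        raise DataError("no analyzed sites after indel-column deletion")

    # segregating sites among the sample, non-indel columns only
    seqs = [aln.sequence(a) for a in uniq]
    S = 0
    indel_cols = 0
    for col in range(aln.alignment_length):
        states = {s[col] for s in seqs}
        if col in skip:
            if "-" in states and len(states) > 1:
                indel_cols += 1
            continue
        if len(states) > 1:
            S += 1

    # k: average over all gene-copy pairs (duplicate copies differ by 0)
    dmat = difference_matrix(aln, uniq)
    cvec = np.array([hap_counts[a] for a in uniq], dtype=float)
    total = float(cvec @ dmat @ cvec) / 2.0  # diagonal is zero
    npairs = n * (n - 1) / 2
    k = total / npairs
    pi = k / L

    p = np.array([c / n for c in hap_counts.values()])
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    hd = (n / (n - 1)) * (1.0 - sum2)
    # Nei (1987) eq. 8.12 sampling variance of heterozygosity/haplotype diversity
    var_hd = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    hd_sd = math.sqrt(max(var_hd, 0.0))
    # Nei (1987) eq. 10.7 variance of pi (no recombination correction)
    var_pi = ((n + 1) / (3.0 * (n - 1) * L)) * pi + (
        2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    ) * pi * pi
    pi_sd = math.sqrt(max(var_pi, 0.0))
    return SeqDiversity(
        n=n, S=S, indel_bp=indel_cols, k=k, hd=hd, hd_sd=hd_sd,
        pi=pi, pi_sd=pi_sd, analyzed_sites=L,
    )


def bootstrap_seq_sd(
    aln: LocusAlignment,
    table: GenotypeTable,
    popmap: PopulationMap,
    locus: str,
    population: str,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, float]:
    """Bootstrap-over-individuals SDs of haplotype and nucleotide diversity,
    offered alongside the closed-form Nei variances."""
    rng = np.random.default_rng() if rng is None else rng
    members = [
        i for i in popmap.members(population) if table.call(i, locus) is not None
    ]
    hds, pis = [], []
    for _ in range(n_boot):
        resampled = rng.choice(members, size=len(members), replace=True)
        copies: list[str] = []
        for ind in resampled:
            copies.extend(a for a in table.call(ind, locus) if a is not None)
        if len(set(copies)) < 1 or len(copies) < 2:
            continue
        st = seq_diversity_stats(aln, copies)
        hds.append(st.hd)
        pis.append(st.pi)
    return {"hd_sd_boot": float(np.std(hds, ddof=1)), "pi_sd_boot": float(np.std(pis, ddof=1))}


# -- APD ---------------------------------------------------------------------

@dataclass
class APDRow:
    population: str
    locus: str
    C: int                      # number of pairwise comparisons N(N-1)/2
    apd: float                  # mean percent difference
    se: float                   # SD of pair values / sqrt(C)
    pair_values: np.ndarray = field(repr=False, default=None)


def allele_multiset(table: GenotypeTable, individual: str, locus: str) -> Counter:
    """The allele multiset an individual contributes to similarity statistics.

    Diploid loci: a homozygote is a size-2 multiset {a, a}; a half-locus call is
    the size-1 multiset of its scored allele.  Multicopy loci: the set of
    distinct detected alleles (sizes 1-4).
    """
    kind = table.loci[locus]
    call = table.call(individual, locus)
    if call is None:
        return Counter()
    if kind == "sequence_multicopy":
        return Counter(dict.fromkeys(call, 1))
    a, b = call
    return Counter([a] if b is None else [a, b])


def dice_similarity(x: Counter, y: Counter) -> float:
    """Dice/Lynch similarity 2*shared / (|x| + |y|) on allele multisets."""
    nx, ny = sum(x.values()), sum(y.values())
    shared = sum((x & y).values())
    return 2.0 * shared / (nx + ny)


def apd(
    table: GenotypeTable,
    popmap: PopulationMap,
    locus: str,
    population: str,
) -> APDRow:
    """Average percent difference across all individual pairwise comparisons."""
    multisets = []
    for ind in popmap.members(population):
        ms = allele_multiset(table, ind, locus)
        if ms:
            multisets.append(ms)
        # individuals with no scored allele are excluded from N
    N = len(multisets)
    if N < 2:
        raise ParameterError("APD needs >= 2 individuals with scored alleles")
    vals = []
    for i in range(N):
        for j in range(i + 1, N):
            vals.append(100.0 * (1.0 - dice_similarity(multisets[i], multisets[j])))
    arr = np.array(vals)
    C = N * (N - 1) // 2
    se = float(np.std(arr, ddof=1) / math.sqrt(C)) if C > 1 else 0.0
    return APDRow(population=population, locus=locus, C=C,
                  apd=float(arr.mean()), se=se, pair_values=arr)


def pair_count(n_individuals: int) -> int:
    """Number of unordered pairwise comparisons C = N(N-1)/2."""
    return n_individuals * (n_individuals - 1) // 2


def nucleotide_diversity_from_k(k: float, analyzed_sites: int) -> float:
    """The identity pi = k / analyzed_sites used throughout the diversity tables."""
    if analyzed_sites < 1:
        raise ParameterError("analyzed_sites must be >= 1")
    return k / analyzed_sites
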