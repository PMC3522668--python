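"""Replicate-PCR consensus genotyping and marker quality control.

Consensus calling follows the comparative multi-tubes protocol: a heterozygote
is accepted once both alleles have each been seen in at least two PCRs, a
homozygote after three concordant homozygous PCRs; on conflict further
replicates are consumed until every reported allele is observed at least
twice, and after at most seven PCRs an unresolved genotype degrades to a
half-locus call (one confirmed allele) or missing.

Also here: genotyping-error rates from paired reference/test samples (e.g.
blood vs fecal), the expectation-maximization null-allele frequency estimator,
a Monte-Carlo exact Hardy-Weinberg test, and a genotypic linkage-
disequilibrium permutation test.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .errors import (
    ConvergenceError,
    DataError,
    ParameterError,
    UndefinedStatisticError,
)
from .io import Call, GenotypeTable

MAX_PCRS = 7


def consensus_genotype(calls: Sequence[tuple]) -> Call:
    """Consensus diploid genotype from ordered replicate PCR calls.

    Returns a full pair, a half-locus call ``(a, None)``, or ``None`` when no
    allele is confirmed.  An allele observed only once is never reported.
    """
    if not calls:
        return None
    counts: Counter = Counter()
    first_seen: dict[str, int] = {}
    processed: list[tuple] = []
    for idx, call in enumerate(calls[:MAX_PCRS], start=1):
        observed = {a for a in call if a is not None}
        for a in observed:
            counts[a] += 1
            first_seen.setdefault(a, idx)
        processed.append(call)
        confirmed = [a for a, c in counts.items() if c >= 2]
        if len(confirmed) >= 2:
            # tie-break: report the two best-supported confirmed alleles
            top2 = sorted(confirmed, key=lambda a: (-counts[a], first_seen[a]))[:2]
            return tuple(sorted(top2))
        if (
            len(counts) == 1
            and idx >= 3
            and all(c[0] == c[1] and c[1] is not None for c in processed)
        ):
            allele = next(iter(counts))
            return (allele, allele)
    confirmed = [a for a, c in counts.items() if c >= 2]
    if len(confirmed) == 1:
        return (confirmed[0], None)
    return None


def consensus_table(
    replicates: Sequence[GenotypeTable],
) -> GenotypeTable:
    """Apply :func:`consensus_genotype` across a stack of replicate tables."""
    if not replicates:
        raise ParameterError("need >= 1 replicate table")
    first = replicates[0]
    out = GenotypeTable(individuals=list(first.individuals), loci=dict(first.loci))
    for ind in first.individuals:
        for locus in first.loci:
            stack = [
                rep.call(ind, locus) for rep in replicates
                if rep.call(ind, locus) is not None
            ]
            out.calls[(ind, locus)] = consensus_genotype(stack)
    return out


@dataclass
class ErrorRates:
    per_locus: dict[str, dict[str, float]]  # locus -> {dropout, false_allele, total}
    dropout: float
    false_allele: float
    total: float
    n_comparisons: int


def genotyping_error_rates(reference: GenotypeTable, test: GenotypeTable) -> ErrorRates:
    """Error rates of ``test`` against ``reference`` over shared full genotypes.

    Allelic dropout: fraction of reference-heterozygous comparisons observed as
    a homozygote for one of the two true alleles.  False allele: fraction of
    comparisons where the test shows an allele absent from the reference.
    Total: fraction of mismatching allele slots (two per genotype).
    Half-locus and missing calls are skipped pairwise.
    """
    shared_loci = [l for l in reference.loci if l in test.loci]
    per_locus: dict[str, dict[str, float]] = {}
    drop_events = het_comps = false_events = comps = slot_err = 0
    for locus in shared_loci:
        ld = lh = lf = lc = ls = 0
        for ind in reference.individuals:
            ref = reference.call(ind, locus)
            obs = test.call(ind, locus)
            if ref is None or obs is None or ref[1] is None or obs[1] is None:
                continue
            lc += 1
            ref_ms, obs_ms = Counter(ref), Counter(obs)
            ls += 2 - sum((ref_ms & obs_ms).values())
            if ref[0] != ref[1]:
                lh += 1
                if obs[0] == obs[1] and obs[0] in ref:
                    ld += 1
            if any(a not in ref for a in obs):
                lf += 1
        if lc:
            per_locus[locus] = {
                "dropout": ld / lh if lh else 0.0,
                "false_allele": lf / lc,
                "total": ls / (2 * lc),
            }
        drop_events += ld
        het_comps += lh
        false_events += lf
        comps += lc
        slot_err += ls
    if comps == 0:
        raise UndefinedStatisticError("no overlapping full-genotype comparisons")
    return ErrorRates(
        per_locus=per_locus,
        dropout=drop_events / het_comps if het_comps else 0.0,
        false_allele=false_events / comps,
        total=slot_err / (2 * comps),
        n_comparisons=comps,
    )


# -- null-allele EM ----------------------------------------------------------

@dataclass
class NullAlleleResult:
    naf: float
    frequencies: dict[str, float]  # visible alleles (null under key NULL)
    n_iter: int
    degenerate: bool = False
    bootstrap: Optional[np.ndarray] = None


NULL = "<null>"


def _em_loglik(
    het: Mapping[tuple, int], hom: Mapping[str, int], n_blank: int,
    p: Mapping[str, float], use_blanks: bool,
) -> float:
    ll = 0.0
    for (a, b), c in het.items():
        ll += c * math.log(max(2 * p[a] * p[b], 1e-300))
    for a, c in hom.items():
        ll += c * math.log(max(p[a] ** 2 + 2 * p[a] * p[NULL], 1e-300))
    if use_blanks and n_blank:
        ll += n_blank * math.log(max(p[NULL] ** 2, 1e-300))
    return ll


def null_allele_em(
    genotype_counts: Mapping[Optional[tuple], int],
    include_missing_as_nullhomozygote: bool = False,
    max_iter: int = 10000,
    tol: float = 1e-8,
    n_boot: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> NullAlleleResult:
    """EM estimate of the null-allele frequency at one locus.

    ``genotype_counts`` maps sorted allele pairs to counts; the key ``None``
    holds the blank (non-amplifying) individuals, used only when
    ``include_missing_as_nullhomozygote`` is set.  Observed homozygotes i/i are
    apportioned between true i/i and i/null at each E-step under
    Hardy-Weinberg; the log-likelihood is non-decreasing across iterations.
    """
    rng = np.random.default_rng() if rng is None else rng
    het: dict[tuple, int] = {}
    hom: dict[str, int] = {}
    n_blank = int(genotype_counts.get(None, 0))
    for g, c in genotype_counts.items():
        if g is None or c == 0:
            continue
        a, b = g
        if b is None:
            raise DataError("half-locus calls are not usable in the EM")
        if a == b:
            hom[a] = hom.get(a, 0) + c
        else:
            key = tuple(sorted((a, b)))
            het[key] = het.get(key, 0) + c
    alleles = sorted({a for g in het for a in g} | set(hom))
    n_geno = sum(het.values()) + sum(hom.values())
    if n_geno == 0:
        if n_blank:
            warnings.warn("all individuals blank: null frequency degenerate at 1")
            return NullAlleleResult(
                naf=1.0, frequencies={NULL: 1.0}, n_iter=0, degenerate=True
            )
        raise DataError("no genotypes")
    if len(alleles) < 2:
        raise DataError("need >= 2 visible alleles")
    use_blanks = include_missing_as_nullhomozygote

    def run_em(het_c, hom_c, blank_c):
        p = {a: 1.0 / (len(alleles) + 1) for a in alleles}
        p[NULL] = 1.0 / (len(alleles) + 1)
        for it in range(1, max_iter + 1):
            counts = {a: 0.0 for a in alleles}
            counts[NULL] = 0.0
            for (a, b), c in het_c.items():
                counts[a] += c
                counts[b] += c
            for a, c in hom_c.items():
                denom = p[a] + 2 * p[NULL]
                w = p[a] / denom if denom > 0 else 1.0  # P(true hom | observed hom)
                counts[a] += c * (1.0 + w)
                counts[NULL] += c * (1.0 - w)
            if use_blanks:
                counts[NULL] += 2.0 * blank_c
            total = sum(counts.values())
            new_p = {a: c / total for a, c in counts.items()}
            delta = max(abs(new_p[a] - p[a]) for a in new_p)
            p = new_p
            if delta < tol:
                return _polish_boundary(het_c, hom_c, blank_c, p, use_blanks), it
        raise ConvergenceError(f"null-allele EM did not converge in {max_iter} iterations")

    def _polish_boundary(het_c, hom_c, blank_c, p, use_blanks):
        # EM approaches the p_null = 0 boundary sublinearly; snap to the
        # boundary when that does not lower the likelihood
        if not 0.0 < p[NULL] < 1e-3:
            return p
        scale = 1.0 - p[NULL]
        p0 = {a: (v / scale if a != NULL else 0.0) for a, v in p.items()}
        if _em_loglik(het_c, hom_c, blank_c, p0, use_blanks) >= _em_loglik(
            het_c, hom_c, blank_c, p, use_blanks
        ) - 1e-9:
            return p0
        return p

    p, n_iter = run_em(het, hom, n_blank)
    boot = None
    if n_boot > 0:
        cats: list[Optional[tuple]] = list(het) + [(a, a) for a in hom]
        weights = np.array([het[c] for c in het] + [hom[a] for a in hom], dtype=float)
        if use_blanks and n_blank:
            cats.append(None)
            weights = np.append(weights, n_blank)
        probs = weights / weights.sum()
        n_ind = int(weights.sum())
        boot_vals = []
        for _ in range(n_boot):
            draw = rng.multinomial(n_ind, probs)
            het_b: dict[tuple, int] = {}
            hom_b: dict[str, int] = {}
            blank_b = 0
            for cat, c in zip(cats, draw):
                if c == 0:
                    continue
                if cat is None:
                    blank_b = int(c)
                elif cat[0] == cat[1]:
                    hom_b[cat[0]] = int(c)
                else:
                    het_b[cat] = int(c)
            if len({a for g in het_b for a in g} | set(hom_b)) < 2:
                continue
            try:
                pb, _ = run_em(het_b, hom_b, blank_b)
            except ConvergenceError:
                continue
            boot_vals.append(pb[NULL])
        boot = np.array(boot_vals)
    return NullAlleleResult(
        naf=p[NULL], frequencies=p, n_iter=n_iter, bootstrap=boot
    )


# -- exact HWE test ----------------------------------------------------------

@dataclass
class HWEResult:
    p: float
    p_het_deficiency: float
    n_mc: int


def hwe_exact_mc(
    genotypes: Sequence[tuple],
    n_mc: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> HWEResult:
    """Monte-Carlo exact Hardy-Weinberg test for one locus in one population.

    Gene copies are shuffled into random pairings (the conditional-on-allele-
    counts null); ``p`` is the proportion of arrays at most as probable as the
    observed one, and the one-sided heterozygote-deficiency p uses the
    heterozygote count as ordering statistic.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_mc < 1:
        raise ParameterError("n_mc must be >= 1")
    full = [g for g in genotypes if g is not None and g[1] is not None]
    if not full:
        raise DataError("no full genotypes")
    copies = [a for g in full for a in g]
    alleles = sorted(set(copies))
    K = len(alleles)
    if K < 2:
        warnings.warn("monomorphic locus: HWE p = 1")
        return HWEResult(p=1.0, p_het_deficiency=1.0, n_mc=0)
    idx = {a: i for i, a in enumerate(alleles)}
    arr = np.array([idx[a] for a in copies])
    n = len(full)

    def stat_and_het(pairs: np.ndarray) -> tuple[float, int]:
        lo = pairs.min(axis=1)
        hi = pairs.max(axis=1)
        gid = lo * K + hi
        cnt = np.bincount(gid, minlength=K * K)
        n_het = int(np.sum(lo != hi))
        # log conditional probability up to constants: H log 2 - sum log n_ij!
        return n_het * math.log(2.0) - float(np.sum(gammaln(cnt + 1.0))), n_het

    obs_stat, obs_het = stat_and_het(arr.reshape(n, 2))
    # vectorized shuffles in chunks
    hits = hits_het = 0
    chunk = max(1, min(n_mc, int(2e6 // max(K * K, 2 * n))))
    done = 0
    while done < n_mc:
        b = min(chunk, n_mc - done)
        mat = np.tile(arr, (b, 1))
        mat = rng.permuted(mat, axis=1).reshape(b, n, 2)
        lo = mat.min(axis=2)
        hi = mat.max(axis=2)
        gid = lo * K + hi
        flat = gid + (np.arange(b)[:, None]) * (K * K)
        cnt = np.bincount(flat.ravel(), minlength=b * K * K).reshape(b, K * K)
        n_het = (lo != hi).sum(axis=1)
        stats = n_het * math.log(2.0) - np.sum(gammaln(cnt + 1.0), axis=1)
        hits += int(np.sum(stats <= obs_stat + 1e-9))
        hits_het += int(np.sum(n_het <= obs_het))
        done += b
    p = (1 + hits) / (n_mc + 1)
    p_def = (1 + hits_het) / (n_mc + 1)
    return HWEResult(p=float(p), p_het_deficiency=float(p_def), n_mc=n_mc)


# -- genotypic LD ------------------------------------------------------------

def ld_permutation_test(
    calls1: Sequence[Call],
    calls2: Sequence[Call],
    n_perm: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Permutation test of genotypic linkage disequilibrium between two loci.

    Statistic: log-likelihood G of the two-locus genotype contingency table;
    the null permutes one locus's genotypes across individuals.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if len(calls1) != len(calls2):
        raise ParameterError("call lists must align on individuals")
    pairs = [
        (g1, g2) for g1, g2 in zip(calls1, calls2)
        if g1 is not None and g2 is not None and g1[1] is not None and g2[1] is not None
    ]
    if not pairs:
        raise DataError("no complete two-locus genotypes")
    g1s = [p[0] for p in pairs]
    g2s = [p[1] for p in pairs]
    cats1 = sorted(set(g1s))
    cats2 = sorted(set(g2s))
    if len(cats1) < 2 or len(cats2) < 2:
        warnings.warn("fewer than 2 genotype categories at a locus: LD p = 1")
        return 1.0
    i1 = np.array([cats1.index(g) for g in g1s])
    i2 = np.array([cats2.index(g) for g in g2s])
    R, C = len(cats1), len(cats2)
    n = len(pairs)

    def g_stat(a: np.ndarray, b: np.ndarray) -> float:
        tab = np.bincount(a * C + b, minlength=R * C).reshape(R, C).astype(float)
        rows = tab.sum(axis=1, keepdims=True)
        cols = tab.sum(axis=0, keepdims=True)
        expected = rows * cols / n
        mask = tab > 0
        return 2.0 * float(np.sum(tab[mask] * np.log(tab[mask] / expected[mask])))

    g_obs = g_stat(i1, i2)
    hits = 0
    for _ in range(n_perm):
        hits += g_stat(i1, rng.permutation(i2)) >= g_obs - 1e-12
    return (1 + hits) / (n_perm + 1)
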