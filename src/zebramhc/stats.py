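"""Group-comparison statistics for the two-population contrast layer.

Kruskal-Wallis rank randomization, Levene's test on absolute residuals to the
group mean, the Wilcoxon rank-sum Z test (normal approximation with tie and
continuity corrections, exact enumeration for small samples), Pearson
chi-square contingency analysis, and the Holm sequential-Bonferroni
correction.  Established scipy routines compute the base statistics; the
randomization machinery around them is local.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

#: exhaustive enumeration is used when the arrangement count is at most this
ENUM_LIMIT = 200000


@dataclass
class GroupComparison:
    statistic: str       # KW_H | Levene_W | Wilcoxon_Z | ChiSq
    value: float
    p: float
    method: str          # randomization | asymptotic | exact
    df: Optional[float] = None
    p_asymptotic: Optional[float] = None


def _kw_h(ranks: np.ndarray, labels: np.ndarray, tie_factor: float) -> float:
    N = len(ranks)
    h = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def kruskal_wallis_randomization(
    values: Sequence[float],
    labels: Sequence,
    n_perm: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> GroupComparison:
    """Kruskal-Wallis H with a randomization p (label permutation); exhaustive
    enumeration replaces sampling when the arrangement count is small.  The
    asymptotic chi-square p is reported alongside."""
    rng = np.random.default_rng() if rng is None else rng
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2 or any(np.sum(labels == g) < 2 for g in groups):
        raise ParameterError("need >= 2 groups with >= 2 values each")
    if np.all(values == values[0]):
        return GroupComparison("KW_H", 0.0, 1.0, "randomization",
                               df=float(len(groups) - 1), p_asymptotic=1.0)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    N = len(values)
    tie_factor = 1.0 - np.sum(tie_counts**3 - tie_counts) / (N**3 - N)
    h_obs = _kw_h(ranks, labels, tie_factor)
    df = float(len(groups) - 1)
    p_asym = float(sps.chi2.sf(h_obs, df))

    sizes = [int(np.sum(labels == g)) for g in groups]
    n_arrangements = math.factorial(N) // math.prod(math.factorial(s) for s in sizes)
    if n_arrangements <= ENUM_LIMIT:
        count = total = 0
        for perm in _multiset_permutations(labels):
            total += 1
            count += _kw_h(ranks, perm, tie_factor) >= h_obs - 1e-12
        p = count / total
        method = "exact"
    else:
        hits = 0
        lab = labels.copy()
        for _ in range(n_perm):
            lab = rng.permutation(lab)
            hits += _kw_h(ranks, lab, tie_factor) >= h_obs - 1e-12
        p = (1 + hits) / (n_perm + 1)
        method = "randomization"
    return GroupComparison("KW_H", float(h_obs), float(p), method,
                           df=df, p_asymptotic=p_asym)


def _multiset_permutations(labels: np.ndarray):
    """Distinct arrangements of the label multiset (via positions of each group)."""
    groups, counts = np.unique(labels, return_counts=True)
    N = len(labels)
    idx = np.arange(N)

    def rec(remaining, gi):
        if gi == len(groups) - 1:
            arr = np.empty(N, dtype=labels.dtype)
            arr[remaining] = groups[gi]
            yield arr.copy(), remaining
            return
        for combo in itertools.combinations(range(len(remaining)), counts[gi]):
            taken = remaining[list(combo)]
            rest = np.delete(remaining, list(combo))
            for arr, _ in rec(rest, gi + 1):
                arr[taken] = groups[gi]
                yield arr, None

    for arr, _ in rec(idx, 0):
        yield arr


def levene_test(values: Sequence[float], labels: Sequence) -> GroupComparison:
    """Levene's test: one-way ANOVA F on absolute residuals to the group mean.
    Zero within-group residual variance with unequal group means flags F as
    infinite."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2 or any(np.sum(labels == g) < 2 for g in groups):
        raise ParameterError("need >= 2 groups with >= 2 values each")
    resid = np.empty_like(values)
    for g in groups:
        mask = labels == g
        resid[mask] = np.abs(values[mask] - values[mask].mean())
    group_resid = [resid[labels == g] for g in groups]
    within_var = sum(float(np.sum((r - r.mean()) ** 2)) for r in group_resid)
    grand = resid.mean()
    between = sum(len(r) * (r.mean() - grand) ** 2 for r in group_resid)
    df1 = len(groups) - 1
    df2 = len(values) - len(groups)
    if within_var == 0.0:
        if between == 0.0:
            return GroupComparison("Levene_W", 0.0, 1.0, "asymptotic", df=float(df1))
        warnings.warn("zero within-group residual variance: Levene F infinite")
        return GroupComparison("Levene_W", math.inf, 0.0, "asymptotic", df=float(df1))
    f = (between / df1) / (within_var / df2)
    p = float(sps.f.sf(f, df1, df2))
    return GroupComparison("Levene_W", float(f), p, "asymptotic", df=float(df1))


def wilcoxon_ranksum_z(values: Sequence[float], labels: Sequence) -> GroupComparison:
    """Two-sample Wilcoxon rank-sum test reported as a Z statistic.

    Normal approximation with tie and continuity corrections; when both groups
    have at most 10 observations the two-sided p comes from exhaustive
    enumeration of label arrangements instead."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ParameterError("need exactly 2 groups")
    n1 = int(np.sum(labels == groups[0]))
    n2 = int(np.sum(labels == groups[1]))
    if n1 == 0 or n2 == 0:
        raise ParameterError("a group is empty")
    ranks = sps.rankdata(values)
    w = float(ranks[labels == groups[0]].sum())
    N = n1 + n2
    mean_w = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((N) * (N - 1))
    var_w = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var_w <= 0:
        return GroupComparison("Wilcoxon_Z", 0.0, 1.0, "asymptotic")
    diff = w - mean_w
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - math.copysign(cc, diff)) / math.sqrt(var_w)
    p_asym = float(2.0 * sps.norm.sf(abs(z)))
    if n1 <= 10 and n2 <= 10:
        count = total = 0
        dev_obs = abs(diff)
        for combo in itertools.combinations(range(N), n1):
            ws = float(ranks[list(combo)].sum())
            total += 1
            count += abs(ws - mean_w) >= dev_obs - 1e-12
        p = count / total
        method = "exact"
    else:
        p = min(1.0, p_asym)
        method = "asymptotic"
    return GroupComparison("Wilcoxon_Z", float(z), float(p), method,
                           p_asymptotic=p_asym)


def chisq_contingency(
    table: Sequence[Sequence[float]],
    n_mc: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> GroupComparison:
    """Pearson chi-square on an R x C count table (no continuity correction);
    optional Monte-Carlo p for sparse tables (margin-preserving resampling)."""
    rng = np.random.default_rng() if rng is None else rng
    tab = np.asarray(table, dtype=float)
    if np.any(tab < 0):
        raise ParameterError("negative counts")
    keep_r = tab.sum(axis=1) > 0
    keep_c = tab.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("zero row/column dropped from contingency table")
        tab = tab[keep_r][:, keep_c]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return GroupComparison("ChiSq", 0.0, 1.0, "asymptotic", df=0.0)
    chi2, p, dof, _ = sps.chi2_contingency(tab, correction=False)
    result = GroupComparison("ChiSq", float(chi2), float(p), "asymptotic",
                             df=float(dof), p_asymptotic=float(p))
    if n_mc > 0:
        # permutation of individual-level column labels, margins preserved
        rows = np.repeat(np.arange(tab.shape[0]), tab.sum(axis=1).astype(int))
        cols = np.repeat(np.arange(tab.shape[1]), tab.sum(axis=0).astype(int))
        hits = 0
        R, C = tab.shape
        for _ in range(n_mc):
            perm = rng.permutation(cols)
            t = np.bincount(rows * C + perm, minlength=R * C).reshape(R, C)
            c2, _, _, _ = sps.chi2_contingency(t, correction=False)
            hits += c2 >= chi2 - 1e-12
        result = GroupComparison("ChiSq", float(chi2), (1 + hits) / (n_mc + 1),
                                 "randomization", df=float(dof), p_asymptotic=float(p))
    return result


def holm_correction(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down (sequential Bonferroni): monotone adjusted p-values and
    rejection decisions at ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ParameterError("need >= 1 p-value")
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj, adj <= alpha
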