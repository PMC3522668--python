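"""Mismatch distributions and sudden-expansion model fitting.

The observed mismatch distribution is the histogram of pairwise nucleotide
difference counts over all gene-copy pairs (indel columns excluded).  The
sudden-expansion model (instantaneous change theta0 -> theta1 at scaled time
tau = 2ut before present) has a closed-form expected distribution

    F_s = Fhat_s(theta1) * Pr(Pois(alpha*tau) > s)
          + exp(-tau/theta1) * sum_{m<=s} Pois(m; tau) * Fhat_{s-m}(theta0)

with Fhat_s(theta) = theta^s / (theta+1)^(s+1) the equilibrium geometric
distribution and alpha = 1 + 1/theta1; the Poisson factors keep the evaluation
stable for any parameter values.  Goodness of fit uses the sum of squared
deviations (SSD) between observed and fitted distributions and Harpending's
raggedness index; significance comes from a parametric bootstrap that
re-simulates coalescent samples under the fitted expansion and refits each.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from ._coalescent import sim_genealogy
from .diversity import pairwise_differences
from .errors import ParameterError
from .io import LocusAlignment

#: classes appended beyond the largest observed difference
TAIL_CLASSES = 5
#: expected-distribution tail is accumulated until this mass is covered
TAIL_EPS = 1e-12


def mismatch_histogram(aln: LocusAlignment, copies: Sequence[str]) -> np.ndarray:
    """Relative frequencies of pairwise difference counts (classes 0..d)."""
    n = len(copies)
    if n < 2:
        raise ParameterError("need >= 2 gene copies")
    from collections import Counter

    from .diversity import difference_matrix

    hap_counts = Counter(copies)
    uniq = list(hap_counts)
    total_pairs = n * (n - 1) / 2.0
    counts: dict[int, float] = {}
    # same-haplotype pairs all fall in class 0
    counts[0] = sum(c * (c - 1) / 2.0 for c in hap_counts.values())
    dmat = difference_matrix(aln, uniq)
    for i, a in enumerate(uniq):
        for j in range(i + 1, len(uniq)):
            d = int(dmat[i, j])
            counts[d] = counts.get(d, 0.0) + hap_counts[a] * hap_counts[uniq[j]]
    dmax = max(counts)
    hist = np.zeros(dmax + 1)
    for d, c in counts.items():
        hist[d] = c / total_pairs
    return hist


def _equilibrium(theta: float, n_classes: int) -> np.ndarray:
    """Fhat_s(theta) = theta^s / (theta+1)^(s+1); point mass at 0 for theta=0."""
    s = np.arange(n_classes)
    if theta <= 0:
        out = np.zeros(n_classes)
        out[0] = 1.0
        return out
    return np.exp(s * math.log(theta) - (s + 1) * math.log(theta + 1.0))


def _poisson_pmf(lam: float, n_classes: int) -> np.ndarray:
    """pmf of Poisson(lam) for 0..n_classes-1 by the stable upward recursion."""
    if lam <= 0:
        out = np.zeros(n_classes)
        out[0] = 1.0
        return out
    m = np.arange(1, n_classes)
    with np.errstate(divide="ignore"):
        logs = np.concatenate(([-lam], -lam + np.cumsum(np.log(lam / m))))
    return np.exp(logs)


def expected_mismatch(
    tau: float, theta0: float, theta1: float, n_classes: int
) -> np.ndarray:
    """Expected sudden-expansion mismatch probabilities for classes 0..n_classes-1."""
    if tau < 0:
        raise ParameterError("tau must be >= 0")
    if theta0 < 0 or theta1 < 0:
        raise ParameterError("theta parameters must be >= 0")
    eq0 = _equilibrium(theta0, n_classes)
    if tau == 0:
        return eq0
    if theta1 <= 0:
        # zero-size recent epoch: everyone coalesces instantly -> all-identical
        out = np.zeros(n_classes)
        out[0] = 1.0
        return out
    alpha_tau = tau * (theta1 + 1.0) / theta1
    eq1 = _equilibrium(theta1, n_classes)
    pois_alpha = _poisson_pmf(alpha_tau, n_classes)
    sf = np.maximum(1.0 - np.cumsum(pois_alpha), 0.0)  # Pr(Pois(alpha*tau) > s)
    part1 = eq1 * sf
    pois_tau = _poisson_pmf(tau, n_classes)
    conv = np.convolve(pois_tau, eq0)[:n_classes]
    part2 = math.exp(-tau / theta1) * conv
    return part1 + part2


def raggedness(hist: np.ndarray) -> float:
    """Harpending-style raggedness, zero-padded at both ends:
    r = sum (x_i - x_{i-1})^2 over i = 0..d+1 with x_{-1} = x_{d+1} = 0."""
    x = np.concatenate(([0.0], np.asarray(hist, dtype=float), [0.0]))
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    boundary: bool  # tau fitted at 0 (degenerate histogram)


def _ssd(params: np.ndarray, hist: np.ndarray) -> float:
    """SSD over the observed difference classes 0..d (trailing zeros already
    trimmed by the caller), matching the standard mismatch goodness-of-fit."""
    tau, theta0, theta1 = params
    d = len(hist)
    F = expected_mismatch(tau, theta0, theta1, d)
    return float(np.sum((hist - F) ** 2))


_THETA1_CAP = 1e5
_TAU_CAP = 1e3
_THETA0_CAP = 1e3


def moment_starts(hist: np.ndarray) -> list[tuple[float, float, float]]:
    """Moment-based multi-start grid around the observed mean difference count.

    Used as the default profile for both the observed fit and the parametric-
    bootstrap refits so the goodness-of-fit comparison is symmetric."""
    m = float(np.sum(np.arange(len(hist)) * np.asarray(hist, dtype=float)))
    m = max(m, 0.5)
    return [
        (m, 0.1, 10.0 * m),
        (0.5 * m, 0.25 * m, m),
        (0.0, m, m),
        (2.0 * m, 0.0, 1e4),
    ]


def fit_sudden_expansion(
    hist: np.ndarray,
    starts: Optional[Sequence[tuple[float, float, float]]] = None,
    full_grid: bool = False,
    maxfun: int = 200,
) -> ExpansionFit:
    """Least-squares fit of (tau, theta0, theta1) to an observed mismatch
    distribution; multi-start local refinement, ties broken by smallest tau.

    The default start profile is the moment grid; ``full_grid`` widens it to a
    27-point product grid for one-off fits where runtime does not matter."""
    hist = np.asarray(hist, dtype=float)
    if len(hist) < 1:
        raise ParameterError("empty histogram")
    hist = np.trim_zeros(hist, "b")  # trailing padding never enters the SSD
    if len(hist) == 0 or hist[0] >= 1.0 - 1e-12:
        # all pairs identical: boundary fit
        return ExpansionFit(tau=0.0, theta0=0.0, theta1=0.0, ssd=0.0, boundary=True)
    m = float(np.sum(np.arange(len(hist)) * hist))  # observed mean differences
    if starts is None and full_grid:
        taus = [max(m, 0.5) * f for f in (0.5, 1.0, 2.0)]
        th0s = [0.0, max(0.25 * m, 0.1), max(m, 0.5)]
        th1s = [max(m, 1.0), 10.0 * max(m, 1.0), 1e4]
        starts = [(t, a, b) for t in taus for a in th0s for b in th1s]
    elif starts is None:
        starts = moment_starts(hist)
    bounds = [(0.0, _TAU_CAP), (0.0, _THETA0_CAP), (0.0, _THETA1_CAP)]
    best = None
    for x0 in starts:
        res = minimize(
            _ssd, np.asarray(x0, dtype=float), args=(hist,),
            method="L-BFGS-B", bounds=bounds, options={"maxfun": maxfun},
        )
        key = (round(res.fun, 12), res.x[0])  # ties broken by smallest tau
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    tau, th0, th1 = (float(v) for v in res.x)
    return ExpansionFit(tau=tau, theta0=th0, theta1=th1, ssd=float(res.fun),
                        boundary=tau <= 1e-9)


def simulate_mismatch_sample(
    n: int,
    fit: ExpansionFit,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pairwise-difference histogram of a coalescent sample simulated under a
    fitted sudden-expansion model."""
    if fit.tau > 0:
        g = sim_genealogy(n, rng, thetas=(fit.theta1, fit.theta0), boundaries=(fit.tau,))
    else:
        g = sim_genealogy(n, rng, thetas=(fit.theta0,))
    n_mut = rng.poisson(g.total_length / 2.0)
    w = g.place_mutations(n_mut, rng)
    # pair differences from branch membership: d_ij = s_i + s_j - 2 (M w) . M
    M = np.zeros((n, len(w)))
    for b, leaves in enumerate(g.branch_leaves):
        M[leaves, b] = 1.0
    s = M @ w
    D = s[:, None] + s[None, :] - 2.0 * (M * w) @ M.T
    iu = np.triu_indices(n, k=1)
    diffs = np.rint(D[iu]).astype(int)
    hist = np.bincount(diffs).astype(float)
    return hist / hist.sum()


@dataclass
class MismatchResult:
    hist: np.ndarray
    fit: ExpansionFit
    r: float
    p_ssd: Optional[float] = None
    p_r: Optional[float] = None
    n_boot: int = 0


def mismatch_bootstrap(
    n: int,
    fit: ExpansionFit,
    observed_ssd: float,
    observed_r: float,
    n_boot: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Parametric-bootstrap p-values for SSD and raggedness.

    Coalescent samples of size ``n`` are simulated under the fitted expansion
    and each is refit with the same moment-start profile the observed fit
    uses (plus the fitted parameters as one extra start), keeping the
    comparison symmetric.  ``p_ssd`` is the proportion of bootstrap SSDs at
    least as large as the observed one; ``p_r`` the analog for raggedness.
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    hits_ssd = hits_r = 0
    for _ in range(n_boot):
        hist = simulate_mismatch_sample(n, fit, rng)
        # identical fitting procedure as the observed side (symmetry)
        refit = fit_sudden_expansion(hist)
        hits_ssd += refit.ssd >= observed_ssd - 1e-15
        hits_r += raggedness(hist) >= observed_r - 1e-15
    p_ssd = (1 + hits_ssd) / (n_boot + 1)
    p_r = (1 + hits_r) / (n_boot + 1)
    return float(p_ssd), float(p_r)


def mismatch_analysis(
    aln: LocusAlignment,
    copies: Sequence[str],
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> MismatchResult:
    """Full mismatch pipeline for one population sample: histogram, expansion
    fit, raggedness, and bootstrap p-values."""
    rng = np.random.default_rng() if rng is None else rng
    hist = mismatch_histogram(aln, copies)
    fit = fit_sudden_expansion(hist)
    r = raggedness(hist)
    p_ssd = p_r = None
    if n_boot > 0:
        p_ssd, p_r = mismatch_bootstrap(
            len(copies), fit, fit.ssd, r, n_boot=n_boot, rng=rng
        )
    return MismatchResult(hist=hist, fit=fit, r=r, p_ssd=p_ssd, p_r=p_r, n_boot=n_boot)
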