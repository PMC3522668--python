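"""Frequency-spectrum and allele-configuration tests of neutrality.

* Tajima's D — contrasts the pairwise-difference estimate of theta with the
  segregating-sites estimate; significance by fixed-S coalescent simulation
  (the tree is drawn from the neutral prior and S mutations are placed on it
  proportionally to branch length — Hudson's fixed-S scheme).
* Fu's F_S — log-odds of observing at least the sampled number of alleles given
  theta estimated from mean pairwise differences, computed with unsigned
  Stirling numbers of the first kind in log space; significance by neutral
  coalescent simulation at theta-hat, lower tail (Fu's convention).
* Ewens–Watterson with Slatkin-style Monte Carlo — observed homozygosity F of
  the allele configuration against its neutral distribution conditional on
  (n, K).  The conditional law is theta-free, so configurations are sampled by
  a Feller-coupling draw of the Ewens sampling formula retained when the allele
  count matches.  Both the homozygosity tail (P_H) and the exact-style tail on
  configuration probability (P_E) are reported.

Monte-Carlo p-values use the add-one convention (1 + #extreme)/(reps + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from ._coalescent import sim_genealogy, sim_infinite_sites, summary_from_matrix
from .errors import ParameterError, UndefinedStatisticError


@dataclass
class AlleleConfiguration:
    """Multiplicities of the distinct alleles in a sample of n gene copies."""

    counts: np.ndarray  # sorted descending

    def __init__(self, counts: Sequence[int]):
        arr = np.sort(np.asarray(counts, dtype=int))[::-1]
        if arr.size < 1 or np.any(arr < 1):
            raise ParameterError("allele multiplicities must be positive")
        self.counts = arr

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def K(self) -> int:
        return int(self.counts.size)

    @property
    def homozygosity(self) -> float:
        """F = sum (n_i/n)^2."""
        p = self.counts / self.n
        return float(np.sum(p * p))


# -- Tajima's D --------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    if n < 4:
        raise ParameterError("Tajima's D needs n >= 4")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, k: float, n: int) -> float:
    """Tajima's D = (k - S/a1) / sqrt(e1*S + e2*S*(S-1))."""
    if S < 1:
        raise UndefinedStatisticError("Tajima's D undefined for S = 0")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (k - S / c["a1"]) / math.sqrt(var)


def tajimas_d_pvalue(
    d_obs: float,
    n: int,
    S: int,
    n_reps: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Two-tailed (equal-tail doubled) p-value from fixed-S simulation."""
    rng = np.random.default_rng() if rng is None else rng
    sims = simulate_tajimas_d_null(n, S, n_reps, rng)
    lo = (1 + np.sum(sims <= d_obs + 1e-12)) / (n_reps + 1)
    hi = (1 + np.sum(sims >= d_obs - 1e-12)) / (n_reps + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def simulate_tajimas_d_null(
    n: int, S: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Fixed-S null sample of Tajima's D (tree prior, S mutations per tree)."""
    c = tajima_constants(n)
    npairs = n * (n - 1) / 2.0
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    out = np.empty(n_reps)
    for r in range(n_reps):
        g = sim_genealogy(n, rng)
        m = g.place_mutations(S, rng)
        k = float(np.sum(m * g.branch_sizes * (n - g.branch_sizes)) / npairs)
        out[r] = (k - S / c["a1"]) / denom
    return out


# -- Fu's F_S ----------------------------------------------------------------

def stirling1_log(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k = 0..n,
    by the recurrence |s(n+1,k)| = n|s(n,k)| + |s(n,k-1)| in log space."""
    if n < 0:
        raise ParameterError("n must be >= 0")
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        shifted = np.concatenate(([-np.inf], row[:n]))  # log|s(m-1, k-1)|
        if m > 1:
            scaled = row + math.log(m - 1)
        else:
            scaled = np.full(n + 1, -np.inf)
        row = np.logaddexp(scaled, shifted)
    row[np.isnan(row)] = -np.inf
    return row


def fus_fs(K: int, k: float, n: int) -> float:
    """Fu's F_S = ln(S' / (1 - S')) with S' = Pr(K' >= K | theta-hat = k)."""
    if K < 2:
        raise UndefinedStatisticError("Fu's F_S undefined for K < 2")
    if k <= 0:
        raise UndefinedStatisticError("Fu's F_S undefined for theta-hat = 0")
    log_s = stirling1_log(n)
    j = np.arange(n + 1)
    log_theta_rising = float(np.sum(np.log(k + np.arange(n))))
    log_terms = log_s + j * math.log(k) - log_theta_rising
    # log Pr(K' = j) for j = 0..n; the j=0 term is -inf
    log_sp = logsumexp(log_terms[K:])
    log_below = logsumexp(log_terms[:K])
    # F_S = log S' - log(1 - S')
    return float(log_sp - log_below)


def fus_fs_pvalue(
    fs_obs: float,
    n: int,
    theta_hat: float,
    n_reps: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """p = Pr(F_S_sim <= F_S_obs) under neutral simulation at theta-hat."""
    rng = np.random.default_rng() if rng is None else rng
    count = 0
    for _ in range(n_reps):
        hap = sim_infinite_sites(n, theta_hat, rng)
        _, k_sim, K_sim, _ = summary_from_matrix(hap)
        if K_sim < 2 or k_sim <= 0:
            fs_sim = math.inf  # monomorphic sample: no allele excess at all
        else:
            fs_sim = fus_fs(K_sim, k_sim, n)
        count += fs_sim <= fs_obs + 1e-12
    return (1 + count) / (n_reps + 1)


# -- Ewens sampling formula --------------------------------------------------

def _log_config_multiplicity(counts: np.ndarray) -> float:
    """log of n! / (prod n_i * prod a_j!) — the (n,K)-conditional Ewens weight
    up to the 1/|s(n,K)| constant."""
    n = int(counts.sum())
    _, mult = np.unique(counts, return_counts=True)
    return (
        gammaln(n + 1)
        - float(np.sum(np.log(counts)))
        - float(np.sum(gammaln(mult + 1)))
    )


def ewens_config_probability(
    config: AlleleConfiguration,
    theta: Optional[float] = None,
    conditional: bool = False,
) -> float:
    """Ewens sampling formula probability of an allele configuration.

    With ``conditional=True`` the probability is conditioned on (n, K):
    P = n! / (|s(n,K)| * prod n_i * prod a_j!) — independent of theta.
    """
    counts = config.counts
    n, K = config.n, config.K
    if conditional:
        log_s = stirling1_log(n)[K]
        return float(math.exp(_log_config_multiplicity(counts) - log_s))
    if theta is None or theta <= 0:
        raise ParameterError("unconditional probability needs theta > 0")
    log_theta_rising = float(np.sum(np.log(theta + np.arange(n))))
    logp = (
        _log_config_multiplicity(counts)
        + K * math.log(theta)
        - log_theta_rising
    )
    return float(math.exp(logp))


def _tune_theta(n: int, K: int) -> float:
    """theta with E[K] = K under the ESF, for efficient conditional rejection."""
    i = np.arange(n)

    def mean_k(log_t: float) -> float:
        t = math.exp(log_t)
        return float(np.sum(t / (t + i))) - K

    if K <= 1:
        return 0.5
    if K >= n:
        return float(n * n)
    return math.exp(brentq(mean_k, -12.0, 12.0))


def sample_ewens_configs(
    n: int,
    K: int,
    n_samples: int,
    rng: np.random.Generator,
    max_batches: int = 2000,
    theta: Optional[float] = None,
) -> list[np.ndarray]:
    """Draw allele configurations from the Ewens distribution conditional on
    (n, K), by Feller-coupling sampling with rejection on the allele count.

    The conditional law is theta-free; ``theta`` only sets the proposal (it is
    tuned to E[K] = K when omitted) and never changes the target distribution.
    """
    if not 1 <= K <= n:
        raise ParameterError("need 1 <= K <= n")
    if K == 1:
        return [np.array([n])] * n_samples
    if K == n:
        return [np.ones(n, dtype=int)] * n_samples
    if theta is None:
        theta = _tune_theta(n, K)
    i = np.arange(1, n + 1)
    p_new = theta / (theta + i - 1.0)  # xi_1 = 1 always
    p_new[0] = 1.0
    configs: list[np.ndarray] = []
    batch = max(256, int(2.5 * n_samples / max(_accept_rate_guess(n, K, theta), 0.02)))
    batch = min(batch, 200000)
    for _ in range(max_batches):
        xi = rng.random((batch, n)) < p_new
        keep = xi.sum(axis=1) == K
        if keep.any():
            # sentinel one at position n: spacings between ones are the part sizes
            sub = np.column_stack([xi[keep], np.ones(int(keep.sum()), dtype=bool)])
            for row in sub:
                configs.append(np.diff(np.flatnonzero(row)))
        if len(configs) >= n_samples:
            return configs[:n_samples]
    raise ParameterError(f"conditional sampler failed to reach K={K} for n={n}")


def _accept_rate_guess(n: int, K: int, theta: float) -> float:
    """Rough normal guess at Pr(K' = K) for batch sizing only."""
    i = np.arange(n)
    var = float(np.sum(theta * i / (theta + i) ** 2))
    if var <= 0:
        return 1.0
    return 1.0 / math.sqrt(2 * math.pi * var)


@dataclass
class EWSResult:
    f_obs: float
    f_exp: float
    p_h: float          # lower tail on homozygosity (balancing-selection side)
    p_h_upper: float
    p_e: float          # exact-style tail on configuration probability
    n_mc: int


def ewens_watterson_slatkin(
    config: AlleleConfiguration,
    n_mc: int = 100000,
    rng: Optional[np.random.Generator] = None,
) -> EWSResult:
    """Ewens–Watterson homozygosity test with Monte-Carlo conditional sampling."""
    rng = np.random.default_rng() if rng is None else rng
    n, K = config.n, config.K
    if K > n:
        raise ParameterError("K cannot exceed n")
    f_obs = config.homozygosity
    if K == 1 or K == n:
        # a single configuration exists; the test is degenerate
        return EWSResult(f_obs=f_obs, f_exp=f_obs, p_h=1.0, p_h_upper=1.0, p_e=1.0, n_mc=0)
    samples = sample_ewens_configs(n, K, n_mc, rng)
    f = np.array([float(np.sum((c / n) ** 2)) for c in samples])
    logw_obs = _log_config_multiplicity(config.counts)
    logw = np.array([_log_config_multiplicity(c) for c in samples])
    f_exp = float(f.mean())
    p_h = (1 + int(np.sum(f <= f_obs + 1e-12))) / (n_mc + 1)
    p_h_upper = (1 + int(np.sum(f >= f_obs - 1e-12))) / (n_mc + 1)
    p_e = (1 + int(np.sum(logw <= logw_obs + 1e-9))) / (n_mc + 1)
    return EWSResult(
        f_obs=f_obs, f_exp=f_exp, p_h=float(p_h), p_h_upper=float(p_h_upper),
        p_e=float(p_e), n_mc=n_mc,
    )


def config_from_copies(copies: Sequence[str]) -> AlleleConfiguration:
    """Allele configuration from a list of sampled gene copies (allele IDs)."""
    from collections import Counter

    return AlleleConfiguration(list(Counter(copies).values()))
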