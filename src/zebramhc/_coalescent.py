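"""Single-population coalescent genealogies with piecewise-constant size.

Time is measured in "mismatch units" of 1/(2u) generations, where u is the
per-sequence mutation rate: a pair of lineages accumulates differences at rate
1 per unit time (1/2 per lineage), and in an epoch of scaled size theta a pair
coalesces at rate 1/theta.  Under a constant theta this gives E[k] = theta and
E[S] = theta * a1, the standard neutral expectations, and a size change
theta0 -> theta1 at time tau reproduces the sudden-expansion mismatch model.

The genealogy is returned as flat branch arrays (length, number of descendant
leaves, leaf membership), which is all the infinite-sites machinery needs:
a mutation on a branch with c descendants is carried by those c leaves and
contributes c*(n-c) pairwise differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass
class Genealogy:
    n: int
    branch_lengths: np.ndarray          # (2n-2,)
    branch_sizes: np.ndarray            # (2n-2,) leaves under each branch
    branch_leaves: list[np.ndarray]     # leaf index arrays per branch
    total_length: float

    def place_mutations(self, n_mut: int, rng: np.random.Generator) -> np.ndarray:
        """Assign mutations to branches proportional to branch length."""
        if n_mut == 0:
            return np.zeros(len(self.branch_lengths), dtype=int)
        w = self.branch_lengths / self.total_length
        return rng.multinomial(n_mut, w)

    def haplotype_matrix(self, mut_per_branch: np.ndarray) -> np.ndarray:
        """0/1 matrix (n leaves x segregating sites), one column per mutation."""
        cols = []
        for b, m in enumerate(mut_per_branch):
            for _ in range(int(m)):
                col = np.zeros(self.n, dtype=np.uint8)
                col[self.branch_leaves[b]] = 1
                cols.append(col)
        if not cols:
            return np.zeros((self.n, 0), dtype=np.uint8)
        return np.column_stack(cols)


def sim_genealogy(
    n: int,
    rng: np.random.Generator,
    thetas=(1.0,),
    boundaries=(),
) -> Genealogy:
    """Simulate one coalescent genealogy for ``n`` gene copies.

    ``thetas[i]`` is the scaled size between ``boundaries[i-1]`` and
    ``boundaries[i]`` (looking backward in time); ``thetas[-1]`` applies beyond
    the last boundary.
    """
    if n < 2:
        raise ParameterError("need n >= 2 gene copies")
    thetas = [float(t) for t in thetas]
    boundaries = [float(b) for b in boundaries]
    if len(thetas) != len(boundaries) + 1:
        raise ParameterError("need len(thetas) == len(boundaries) + 1")
    if any(t < 0 for t in thetas) or any(b < 0 for b in boundaries):
        raise ParameterError("negative epoch parameter")

    active: list[np.ndarray] = [np.array([i]) for i in range(n)]
    births = [0.0] * n
    lens: list[float] = []
    sizes: list[int] = []
    leaves: list[np.ndarray] = []

    t = 0.0
    epoch = 0
    j = n
    while j > 1:
        while True:
            theta = thetas[epoch]
            if theta == 0.0:
                # instantaneous coalescence in a zero-size epoch
                w = 0.0
            else:
                rate = j * (j - 1) / 2.0 / theta
                w = rng.exponential(1.0 / rate)
            if epoch < len(boundaries) and t + w > boundaries[epoch]:
                t = boundaries[epoch]
                epoch += 1
                continue
            t += w
            break
        i1, i2 = rng.choice(j, size=2, replace=False)
        if i1 > i2:
            i1, i2 = i2, i1
        for idx in (i2, i1):  # pop larger index first
            lens.append(t - births[idx])
            leaves.append(active[idx])
            sizes.append(len(active[idx]))
        merged = np.concatenate([active[i1], active[i2]])
        # remove i2 then i1, append merged lineage
        del active[i2], births[i2]
        del active[i1], births[i1]
        active.append(merged)
        births.append(t)
        j -= 1

    lengths = np.array(lens)
    return Genealogy(
        n=n,
        branch_lengths=lengths,
        branch_sizes=np.array(sizes),
        branch_leaves=leaves,
        total_length=float(lengths.sum()),
    )


def sim_infinite_sites(
    n: int,
    theta: float,
    rng: np.random.Generator,
    thetas=None,
    boundaries=(),
) -> np.ndarray:
    """Haplotype 0/1 matrix for a neutral sample with mutation rate set so that
    a constant-size population has E[pairwise differences] = theta.

    When ``thetas``/``boundaries`` are given they define the demography and
    ``theta`` is ignored for coalescence (mutation rate is fixed at 1/2 per
    lineage per unit time in all cases)."""
    if thetas is None:
        thetas = (theta,)
    g = sim_genealogy(n, rng, thetas=thetas, boundaries=boundaries)
    n_mut = rng.poisson(g.total_length / 2.0)
    return g.haplotype_matrix(g.place_mutations(n_mut, rng))


def summary_from_matrix(hap: np.ndarray) -> tuple[int, float, int, np.ndarray]:
    """(S, k, K, allele configuration) from a 0/1 haplotype matrix."""
    n = hap.shape[0]
    derived = hap.sum(axis=0)
    seg = (derived > 0) & (derived < n)
    S = int(seg.sum())
    d = derived[seg].astype(float)
    npairs = n * (n - 1) / 2.0
    k = float((d * (n - d)).sum() / npairs)
    # allele configuration from distinct rows
    _, counts = np.unique(hap[:, seg], axis=0, return_counts=True)
    config = np.sort(counts)[::-1]
    return S, k, len(config), config
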