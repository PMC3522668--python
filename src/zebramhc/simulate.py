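"""Two-population synthetic datasets with the statistical structure the
analyses assume.

The generator emulates a field study of two park-separated zebra populations:
13 stepwise-mutating microsatellites, one long neutral intron with an indel
polymorphism, one single-copy MHC exon, one possibly duplicated MHC locus
yielding 1-4 detected alleles per individual, and fecal-DNA genotyping error
(per-PCR allelic dropout and false alleles).

Engines: neutral sequence loci use msprime (2-deme island-model coalescent
with infinite-sites mutations mapped onto distinct columns of an L-bp
sequence); loci under selection use a hand-written forward-time Wright-Fisher
model (multiallelic symmetric overdominance has no simple coalescent); the
single-population sudden-expansion sampler lives in ``_coalescent``.

Every operation takes an explicit ``numpy`` Generator or derives one from the
scenario seed, and fixed seeds reproduce output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import msprime
import numpy as np

from ._coalescent import sim_genealogy
from .errors import DataError, ParameterError
from .io import GenotypeTable, LocusAlignment, PopulationMap

BASES = np.array(list("ACGT"))


@dataclass
class SeqLocusSpec:
    """One sequence locus of the scenario."""

    locus_id: str
    length_bp: int
    theta: float                     # scaled locus mutation rate 4*N_e*u
    kind: str = "sequence_diploid"   # or "sequence_multicopy"
    selection: str = "neutral"       # neutral | overdominant | skewed
    s: float = 0.0                   # homozygote fitness cost under overdominance
    skew_target: float = 0.44        # pinned top-allele frequency (skewed mode)
    indel_bp: int = 0                # length of one segregating indel block


@dataclass
class SimScenario:
    """Full parameterization of the synthetic two-population study.

    Defaults mirror the emulated study design: two populations with roughly
    36 and 31 successfully typed individuals, 13 microsatellites, a 668-bp
    intron carrying a 14-bp indel polymorphism, a 246-bp single-copy MHC exon,
    a 205-bp possibly duplicated MHC locus, and low per-PCR fecal-genotyping
    error (dropout larger than false-allele generation).
    """

    n_individuals: tuple[int, int] = (36, 31)
    population_names: tuple[str, str] = ("pop1", "pop2")
    n_msat_loci: int = 13
    msat_mu: float = 5e-4            # stepwise mutations per gamete per generation
    deme_size: int = 500             # N_e diploids per deme (forward model)
    migration_rate: float = 0.01     # per-gamete per-generation island migration
    burn_in_factor: int = 10         # forward burn-in = factor * deme_size
    seq_loci: tuple[SeqLocusSpec, ...] = (
        SeqLocusSpec("bfib", 668, theta=1.0, indel_bp=14),
        SeqLocusSpec("dra", 246, theta=2.3, selection="overdominant", s=0.3),
        SeqLocusSpec("dqa", 205, theta=15.0, kind="sequence_multicopy"),
    )
    ia_mu: float = 2.5e-3            # infinite-alleles rate for forward selection loci
    detection_dropout: float = 0.35  # per allele copy, multicopy detection
    pcr_dropout: float = 0.05        # per true allele per PCR (heterozygotes)
    pcr_false: float = 0.01          # per PCR false-allele substitution
    n_pcr: int = 3
    expansion_tau: float = 5.0
    expansion_theta0: float = 1.0
    expansion_theta1: float = 100.0
    expansion_n: int = 50
    seed: int = 1729

    def __post_init__(self) -> None:
        for name, rate in (
            ("msat_mu", self.msat_mu), ("migration_rate", self.migration_rate),
            ("detection_dropout", self.detection_dropout),
            ("pcr_dropout", self.pcr_dropout), ("pcr_false", self.pcr_false),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.deme_size < max(self.n_individuals):
            raise ParameterError("deme_size must be >= sampled individuals")
        for spec in self.seq_loci:
            if spec.selection == "overdominant" and not 0.0 <= spec.s <= 1.0:
                raise ParameterError("selection coefficient s must be in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


# -- microsatellites ---------------------------------------------------------

def simulate_msat_two_pop(
    scenario: SimScenario,
    rng: Optional[np.random.Generator] = None,
    n_loci: Optional[int] = None,
) -> tuple[GenotypeTable, PopulationMap]:
    """Forward-time Wright-Fisher island model (2 demes) with stepwise
    microsatellite mutation; burn-in of ``burn_in_factor * deme_size``
    generations from a monomorphic start, then ``n_individuals`` diploids
    sampled per deme."""
    rng = scenario.rng(1) if rng is None else rng
    N = scenario.deme_size
    L = scenario.n_msat_loci if n_loci is None else n_loci
    m = scenario.migration_rate
    mu = scenario.msat_mu
    # allele-size state: (deme, individual, chromosome, locus)
    state = np.full((2, N, 2, L), 100, dtype=np.int16)
    generations = scenario.burn_in_factor * N
    for _ in range(generations):
        new = np.empty_like(state)
        for d in range(2):
            src = np.where(rng.random((N, 2, L)) < m, 1 - d, d)
            parent = rng.integers(0, N, size=(N, 2, L))
            chrom = rng.integers(0, 2, size=(N, 2, L))
            loci = np.broadcast_to(np.arange(L), (N, 2, L))
            new[d] = state[src, parent, chrom, loci]
        mut = rng.random(new.shape) < mu
        steps = rng.choice(np.array([-1, 1], dtype=np.int16), size=new.shape)
        new[mut] += steps[mut]
        state = new

    individuals: list[str] = []
    assignments: dict[str, str] = {}
    loci = {f"msat{l + 1:02d}": "microsatellite" for l in range(L)}
    table = GenotypeTable(individuals=[], loci=loci)
    for d, (pop, n_samp) in enumerate(zip(scenario.population_names, scenario.n_individuals)):
        chosen = rng.choice(N, size=n_samp, replace=False)
        for j, idx in enumerate(chosen):
            ind = f"{pop}_i{j + 1:03d}"
            individuals.append(ind)
            assignments[ind] = pop
            for l, locus in enumerate(loci):
                a, b = state[d, idx, 0, l], state[d, idx, 1, l]
                table.calls[(ind, locus)] = tuple(sorted((str(a), str(b))))
    table.individuals = individuals
    return table, PopulationMap(assignments)


# -- neutral sequence loci ---------------------------------------------------

def _alignment_from_binary(
    locus_id: str,
    hap: np.ndarray,
    length_bp: int,
    rng: np.random.Generator,
) -> tuple[LocusAlignment, np.ndarray]:
    """Collapse a 0/1 haplotype matrix to unique alleles on an L-bp sequence.

    Returns the alignment plus the per-copy allele index.  Raises when the
    number of segregating sites exceeds the sequence capacity."""
    n, S = hap.shape
    if S > length_bp:
        raise DataError(f"{locus_id}: {S} segregating sites exceed {length_bp} bp")
    uniq, inverse = np.unique(hap, axis=0, return_inverse=True)
    # order alleles by frequency (desc) for stable, readable IDs
    freq = np.bincount(inverse, minlength=len(uniq))
    order = np.argsort(-freq, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    inverse = rank[inverse]
    uniq = uniq[order]
    base = _random_sequence(length_bp, rng)
    cols = rng.choice(length_bp, size=S, replace=False)
    derived = np.array(
        [rng.choice([b for b in "ACGT" if b != base[c]]) for c in cols]
    )
    seqs = []
    for row in uniq:
        seq = base.copy()
        seq[cols[row == 1]] = derived[row == 1]
        seqs.append("".join(seq))
    ids = [f"{locus_id}*{i + 1:02d}" for i in range(len(uniq))]
    aln = LocusAlignment(locus_id=locus_id, allele_ids=ids, sequences=seqs)
    return aln, inverse


def _apply_indel(
    aln: LocusAlignment,
    carrier_alleles: np.ndarray,
    indel_bp: int,
    rng: np.random.Generator,
) -> LocusAlignment:
    """Give the carrier alleles a contiguous deletion of ``indel_bp`` columns."""
    L = aln.alignment_length
    start = int(rng.integers(0, L - indel_bp + 1))
    seqs = []
    for i, s in enumerate(aln.sequences):
        if i in carrier_alleles:
            s = s[:start] + "-" * indel_bp + s[start + indel_bp:]
        seqs.append(s)
    return LocusAlignment(locus_id=aln.locus_id, allele_ids=list(aln.allele_ids), sequences=seqs)


def simulate_seq_two_pop(
    scenario: SimScenario,
    spec: SeqLocusSpec,
    rng: Optional[np.random.Generator] = None,
    n_demes: int = 2,
) -> tuple[LocusAlignment, GenotypeTable, PopulationMap]:
    """Neutral coalescent sequence locus: 2 demes with symmetric migration
    (msprime island model) or a single panmictic deme, infinite-sites
    mutations mapped to distinct columns, haplotypes collapsed to alleles and
    paired into diploid genotypes within demes."""
    rng = scenario.rng(2) if rng is None else rng
    N = scenario.deme_size
    mu = spec.theta / (4.0 * N)
    if n_demes == 2:
        demography = msprime.Demography.island_model(
            initial_size=[N, N], migration_rate=scenario.migration_rate
        )
        samples = {
            0: scenario.n_individuals[0],
            1: scenario.n_individuals[1],
        }
    else:
        demography = msprime.Demography.isolated_model(initial_size=[N])
        samples = {0: sum(scenario.n_individuals)}
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        ploidy=2,
        sequence_length=1.0,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        discrete_genome=False,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    n_copies = ts.num_samples
    hap = np.zeros((n_copies, ts.num_sites), dtype=np.uint8)
    for v in ts.variants():
        hap[:, v.site.id] = np.minimum(v.genotypes, 1)
    aln, allele_of_copy = _alignment_from_binary(spec.locus_id, hap, spec.length_bp, rng)
    if spec.indel_bp > 0:
        carriers = _pick_indel_carriers(ts, aln, allele_of_copy, rng)
        aln = _apply_indel(aln, carriers, spec.indel_bp, rng)

    individuals: list[str] = []
    assignments: dict[str, str] = {}
    table = GenotypeTable(individuals=[], loci={spec.locus_id: "sequence_diploid"})
    pop_of_node = {n: ts.node(n).population for n in ts.samples()}
    sample_nodes = list(ts.samples())
    by_ind: dict[int, list[int]] = {}
    for node in sample_nodes:
        ind_id = ts.node(node).individual
        by_ind.setdefault(ind_id, []).append(node)
    counters = {0: 0, 1: 0}
    node_index = {n: i for i, n in enumerate(sample_nodes)}
    for ind_id, nodes in sorted(by_ind.items()):
        d = pop_of_node[nodes[0]] if n_demes == 2 else 0
        pop = scenario.population_names[d] if n_demes == 2 else scenario.population_names[0]
        counters[d] += 1
        name = f"{pop}_s{counters[d]:03d}"
        individuals.append(name)
        assignments[name] = pop
        a1 = aln.allele_ids[allele_of_copy[node_index[nodes[0]]]]
        a2 = aln.allele_ids[allele_of_copy[node_index[nodes[1]]]]
        table.calls[(name, spec.locus_id)] = tuple(sorted((a1, a2)))
    table.individuals = individuals
    return aln, table, PopulationMap(assignments)


def _pick_indel_carriers(
    ts, aln: LocusAlignment, allele_of_copy: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Drop one indel 'mutation' on the genealogy at position 0: pick a branch
    proportional to length; alleles wholly carried by its descendants get the
    deletion (an allele split across carrier and non-carrier copies keeps the
    ancestral state so allele IDs stay consistent)."""
    tree = ts.first()
    nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
    lengths = np.array([tree.branch_length(u) for u in nodes])
    sample_nodes = list(ts.samples())
    node_index = {n: i for i, n in enumerate(sample_nodes)}
    n_alleles = len(aln.allele_ids)
    allele_copies = [
        set(np.flatnonzero(allele_of_copy == a)) for a in range(n_alleles)
    ]
    for _ in range(50):
        branch = nodes[int(rng.choice(len(nodes), p=lengths / lengths.sum()))]
        below = {node_index[s] for s in tree.samples(branch) if s in node_index}
        carriers = [
            a for a in range(n_alleles)
            if allele_copies[a] and allele_copies[a] <= below
        ]
        if 0 < len(carriers) < n_alleles:
            return np.array(carriers, dtype=int)
    # fallback: hang the indel off one allele picked at random
    return np.array([int(rng.integers(0, n_alleles))], dtype=int)


# -- selection loci (forward time) -------------------------------------------

def simulate_balancing_locus(
    scenario: SimScenario,
    spec: SeqLocusSpec,
    rng: Optional[np.random.Generator] = None,
) -> tuple[LocusAlignment, GenotypeTable, PopulationMap]:
    """Forward-time multiallelic locus in a 2-deme island model.

    ``overdominant``: heterozygote fitness 1, homozygote 1 - s, infinite-alleles
    mutation.  ``skewed`` is a phenomenological mode that first runs the
    neutral/overdominant dynamics and then pins the top allele of deme 1 at the
    target frequency (emulating spatially heterogeneous selection without a
    mechanistic model).  ``neutral`` (or s = 0) is plain drift.
    """
    rng = scenario.rng(3) if rng is None else rng
    if spec.selection == "overdominant" and not 0.0 <= spec.s <= 1.0:
        raise ParameterError("s must be in [0, 1]")
    N = scenario.deme_size
    m = scenario.migration_rate
    mu = scenario.ia_mu
    s = spec.s if spec.selection == "overdominant" else 0.0
    state = np.zeros((2, N, 2), dtype=np.int64)  # allele labels
    next_label = 1
    generations = scenario.burn_in_factor * N
    for _ in range(generations):
        het = state[:, :, 0] != state[:, :, 1]
        fitness = np.where(het, 1.0, 1.0 - s)
        probs = [fitness[d] / fitness[d].sum() for d in range(2)]
        new = np.empty_like(state)
        for d in range(2):
            src = np.where(rng.random((N, 2)) < m, 1 - d, d)
            parent = np.empty((N, 2), dtype=np.int64)
            for sd in range(2):
                mask = src == sd
                k = int(mask.sum())
                if k:
                    parent[mask] = rng.choice(N, size=k, p=probs[sd])
            chrom = rng.integers(0, 2, size=(N, 2))
            new[d] = state[src, parent, chrom]
        n_mut = rng.binomial(new.size, mu)
        if n_mut:
            flat = rng.choice(new.size, size=n_mut, replace=False)
            new.ravel()[flat] = np.arange(next_label, next_label + n_mut)
            next_label += n_mut
        state = new

    # sample individuals per deme
    genotypes: list[tuple[int, int, int]] = []  # (deme, a, b)
    for d, n_samp in enumerate(scenario.n_individuals):
        chosen = rng.choice(N, size=n_samp, replace=False)
        for idx in chosen:
            genotypes.append((d, int(state[d, idx, 0]), int(state[d, idx, 1])))

    if spec.selection == "skewed":
        genotypes = _pin_top_allele(genotypes, spec.skew_target, rng)

    labels = sorted({a for _, a, b in genotypes} | {b for _, a, b in genotypes})
    aln = _sequences_for_labels(spec.locus_id, labels, spec.length_bp, rng)
    id_of = dict(zip(labels, aln.allele_ids))
    individuals, assignments = [], {}
    table = GenotypeTable(individuals=[], loci={spec.locus_id: "sequence_diploid"})
    counters = [0, 0]
    for d, a, b in genotypes:
        pop = scenario.population_names[d]
        counters[d] += 1
        name = f"{pop}_b{counters[d]:03d}"
        individuals.append(name)
        assignments[name] = pop
        table.calls[(name, spec.locus_id)] = tuple(sorted((id_of[a], id_of[b])))
    table.individuals = individuals
    return aln, table, PopulationMap(assignments)


def _pin_top_allele(
    genotypes: list[tuple[int, int, int]], target: float, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Rebuild deme-0 genotypes so the most common allele sits at the target
    frequency; remaining copies resampled from the other observed alleles."""
    from collections import Counter

    deme0 = [(a, b) for d, a, b in genotypes if d == 0]
    rest = [(d, a, b) for d, a, b in genotypes if d != 0]
    copies = [a for ab in deme0 for a in ab]
    counts = Counter(copies)
    top = counts.most_common(1)[0][0]
    others = np.array([a for a in copies if a != top])
    if len(others) == 0:
        return genotypes
    n_copies = len(copies)
    n_top = int(round(target * n_copies))
    pool = np.concatenate(
        [np.full(n_top, top), rng.choice(others, size=n_copies - n_top, replace=True)]
    )
    pool = rng.permutation(pool)
    rebuilt = [
        (0, int(pool[2 * i]), int(pool[2 * i + 1])) for i in range(len(deme0))
    ]
    return rebuilt + rest


def _sequences_for_labels(
    locus_id: str, labels: Sequence[int], length_bp: int, rng: np.random.Generator
) -> LocusAlignment:
    """Distinct phenomenological sequences for forward-sim allele labels: each
    allele differs from a random base sequence at its own small random site set."""
    base = _random_sequence(length_bp, rng)
    seen: set[str] = set()
    seqs = []
    for _ in labels:
        for _attempt in range(100):
            k = 1 + rng.poisson(3)
            cols = rng.choice(length_bp, size=min(k, length_bp), replace=False)
            seq = base.copy()
            for c in cols:
                seq[c] = rng.choice([b for b in "ACGT" if b != seq[c]])
            joined = "".join(seq)
            if joined not in seen:
                seen.add(joined)
                seqs.append(joined)
                break
        else:
            raise DataError("could not generate distinct allele sequences")
    ids = [f"{locus_id}*{i + 1:02d}" for i in range(len(labels))]
    return LocusAlignment(locus_id=locus_id, allele_ids=ids, sequences=seqs)


# -- multicopy genotypes -----------------------------------------------------

def simulate_multicopy_genotypes(
    scenario: SimScenario,
    base: GenotypeTable,
    rng: Optional[np.random.Generator] = None,
    loci: Optional[tuple[str, str]] = None,
    out_locus: str = "dqa",
) -> GenotypeTable:
    """Pair two underlying diploid loci into one multicopy locus and apply
    per-allele-copy detection dropout; each individual ends with the set of
    distinct detected alleles (1-4), or a missing call when nothing amplifies."""
    rng = scenario.rng(4) if rng is None else rng
    diploid = [l for l, k in base.loci.items() if k == "sequence_diploid"]
    if loci is None:
        if len(diploid) < 2:
            raise ParameterError("base table needs two sequence_diploid loci")
        loci = (diploid[0], diploid[1])
    p_detect = 1.0 - scenario.detection_dropout
    out = GenotypeTable(
        individuals=list(base.individuals), loci={out_locus: "sequence_multicopy"}
    )
    for ind in base.individuals:
        copies: list[str] = []
        for locus in loci:
            call = base.call(ind, locus)
            if call is None:
                continue
            copies.extend(a for a in call if a is not None)
        detected = sorted({a for a in copies if rng.random() < p_detect})
        out.calls[(ind, out_locus)] = tuple(detected[:4]) if detected else None
    return out


def simulate_multicopy_two_pop(
    scenario: SimScenario,
    spec: SeqLocusSpec,
    rng: Optional[np.random.Generator] = None,
) -> tuple[LocusAlignment, GenotypeTable, PopulationMap]:
    """Multicopy locus from one shared coalescent allele pool: simulate the
    sequence locus for twice as many individuals, pair consecutive individuals
    into the two underlying gene copies, then thin with detection dropout."""
    rng = scenario.rng(5) if rng is None else rng
    doubled = replace(
        scenario,
        n_individuals=(2 * scenario.n_individuals[0], 2 * scenario.n_individuals[1]),
    )
    aln, table2, popmap2 = simulate_seq_two_pop(doubled, spec, rng=rng)
    base = GenotypeTable(
        individuals=[],
        loci={f"{spec.locus_id}_c1": "sequence_diploid", f"{spec.locus_id}_c2": "sequence_diploid"},
    )
    individuals, assignments = [], {}
    for pop, n_samp in zip(scenario.population_names, scenario.n_individuals):
        members = popmap2.members(pop)
        for j in range(n_samp):
            name = f"{pop}_m{j + 1:03d}"
            individuals.append(name)
            assignments[name] = pop
            base.calls[(name, f"{spec.locus_id}_c1")] = table2.call(members[2 * j], spec.locus_id)
            base.calls[(name, f"{spec.locus_id}_c2")] = table2.call(members[2 * j + 1], spec.locus_id)
    base.individuals = individuals
    multi = simulate_multicopy_genotypes(
        scenario, base, rng=rng, out_locus=spec.locus_id
    )
    return aln, multi, PopulationMap(assignments)


# -- PCR replicates ----------------------------------------------------------

def generate_pcr_replicates(
    truth: GenotypeTable,
    dropout: float,
    false_rate: float,
    n_pcr: int,
    rng: Optional[np.random.Generator] = None,
    allele_pool: Optional[dict[str, list[str]]] = None,
) -> list[GenotypeTable]:
    """Per-PCR replicate call tables for diploid loci.

    Each true allele of a heterozygote drops independently with the dropout
    rate; a PCR where both alleles drop still amplifies one of them (chosen at
    random), so any dropout event shows as a homozygote.  Independently, with
    the false-allele rate one observed allele is replaced by a random other
    allele from the locus pool.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not 0 <= dropout <= 1 or not 0 <= false_rate <= 1:
        raise ParameterError("rates must be in [0, 1]")
    loci = [l for l, k in truth.loci.items() if k != "sequence_multicopy"]
    if allele_pool is None:
        allele_pool = {
            l: sorted(
                {
                    a
                    for ind in truth.individuals
                    for a in truth.alleles_of(ind, l)
                }
            )
            for l in loci
        }
    replicates = []
    for _ in range(n_pcr):
        rep = GenotypeTable(
            individuals=list(truth.individuals),
            loci={l: truth.loci[l] for l in loci},
        )
        for ind in truth.individuals:
            for locus in loci:
                call = truth.call(ind, locus)
                if call is None or call[1] is None:
                    rep.calls[(ind, locus)] = call
                    continue
                a, b = call
                if a != b:
                    drop_a = rng.random() < dropout
                    drop_b = rng.random() < dropout
                    if drop_a and drop_b:
                        kept = a if rng.random() < 0.5 else b
                        obs = [kept, kept]
                    elif drop_a:
                        obs = [b, b]
                    elif drop_b:
                        obs = [a, a]
                    else:
                        obs = [a, b]
                else:
                    obs = [a, b]
                if false_rate > 0 and rng.random() < false_rate:
                    pool = [x for x in allele_pool[locus] if x not in obs]
                    if pool:
                        slot = int(rng.integers(0, 2))
                        obs[slot] = pool[int(rng.integers(0, len(pool)))]
                rep.calls[(ind, locus)] = tuple(sorted(obs))
        replicates.append(rep)
    return replicates


# -- sudden expansion --------------------------------------------------------

def simulate_expansion(
    scenario: SimScenario,
    rng: Optional[np.random.Generator] = None,
    locus_id: str = "expansion",
    length_bp: int = 668,
) -> LocusAlignment:
    """Coalescent sample under instantaneous growth theta0 -> theta1 at scaled
    time tau; one FASTA record per sampled gene copy."""
    rng = scenario.rng(6) if rng is None else rng
    tau = scenario.expansion_tau
    if tau < 0:
        raise ParameterError("tau must be >= 0")
    n = scenario.expansion_n
    if tau > 0:
        g = sim_genealogy(
            n, rng, thetas=(scenario.expansion_theta1, scenario.expansion_theta0),
            boundaries=(tau,),
        )
    else:
        g = sim_genealogy(n, rng, thetas=(scenario.expansion_theta0,))
    n_mut = rng.poisson(g.total_length / 2.0)
    hap = g.haplotype_matrix(g.place_mutations(n_mut, rng))
    S = hap.shape[1]
    if S > length_bp:
        raise DataError(f"{S} segregating sites exceed {length_bp} bp capacity")
    base = _random_sequence(length_bp, rng)
    cols = rng.choice(length_bp, size=S, replace=False)
    derived = np.array([rng.choice([b for b in "ACGT" if b != base[c]]) for c in cols])
    seqs = []
    for row in hap:
        seq = base.copy()
        seq[cols[row == 1]] = derived[row == 1]
        seqs.append("".join(seq))
    ids = [f"c{i + 1:03d}" for i in range(n)]
    return LocusAlignment(locus_id=locus_id, allele_ids=ids, sequences=seqs)
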