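# Methods

This note documents the models, estimators and numerical choices behind the
package, in the spirit of a statistical-software methods appendix.  The system
being emulated is a two-population study of immune-gene (MHC class II) versus
neutral variation: two park-separated ungulate populations genotyped at 13
stepwise microsatellites, a 668-bp neutral intron with a 14-bp indel
polymorphism, a 246-bp single-copy MHC exon, and a 205-bp possibly duplicated
MHC locus yielding 1–4 distinct alleles per individual, with part of the
samples derived from fecal DNA and therefore subject to allelic dropout and
false alleles.

## Data model

All pairwise sequence statistics use **complete deletion of indel columns**:
a column is an indel column if any haplotype in the alignment carries a gap,
and `analyzed_sites = alignment_length − #indel_columns`.  Allele identity,
by contrast, **includes indel state** — two haplotypes with different gap
patterns are different alleles — so π and k are computed on substitutions
only while heterozygosity and allele counts see the length polymorphism.
This reproduces the per-locus arithmetic π = k / analyzed_sites of the
emulated study's diversity tables.

Diploid calls are unordered pairs; a *half-locus* call carries one scored
allele and one missing slot and contributes one gene copy to allele
frequencies (multi-tubes genotyping protocols emit these when only one allele
of a genotype can be confirmed; counting the scored allele once keeps
frequencies unbiased under random dropout).  Multicopy calls are sets of 1–4 distinct
allele IDs; the **count-once rule** estimates allele frequencies when copy
number is unknown: a single-allele individual contributes two copies of that
allele, an individual with ≥2 distinct alleles contributes one copy of each.
This deflates common and inflates rare allele frequencies, which is why the
frequency-free APD statistic is always carried alongside.

## Diversity

* Rarefied allelic richness: hypergeometric expectation
  A_g = Σ_i [1 − C(n−n_i, g)/C(n, g)], exact integer binomials; the
  rarefaction unit is gene copies and cross-population tables rarefy at the
  smallest per-population copy count.
* Heterozygosity: plain 1 − Σp² and the n/(n−1) unbiased version; H_O is the
  heterozygote fraction of full diploid genotypes (undefined for multicopy
  loci).
* Sequence diversity: k is the mean pairwise difference over gene copies
  (each diploid contributes both copies), π = k/analyzed_sites; haplotype
  diversity H_D = (n/(n−1))(1 − Σp_h²) with Nei's (1987) eq. 8.12 sampling
  variance, π with Nei's eq. 10.7 variance (no-recombination term omitted);
  a bootstrap-over-individuals SD is available as an empirical alternative.
* APD: for individuals with allele multisets x, y (a diploid homozygote is
  {a,a}; multicopy individuals contribute their allele set), pair similarity
  is the Dice coefficient 2|x∩y|/(|x|+|y|); APD is the mean of
  100·(1−similarity) over all C = N(N−1)/2 pairs, SE = SD/√C.  The same Dice
  kernel underlies F′, so APD and F′ are mutually consistent by construction.

## Differentiation

* Weir–Cockerham θ (1984) per allele and summed over alleles/loci; bootstrap
  CI over loci (percentile, default 10,000); permutation p-values move whole
  individuals between populations (conservative under within-individual
  correlation).  Monomorphic loci contribute zero components and are excluded
  from multilocus sums with a warning.
* AMOVA Φ_ST: two-level variance decomposition on squared inter-haplotype
  distances; the Kimura-2-parameter distance (transitions/transversions with
  pairwise gap exclusion) is used directly as the squared distance,
  Arlequin-style; the 0/1 identity distance recovers the conventional
  haplotype F_ST (verified exactly against the frequency algebra).
  Saturated (infinite) K2P distances abort the AMOVA rather than propagate.
* Jost's D_est: Nei–Chesser nearly unbiased H_S (harmonic-mean gene-copy
  sample size) and H_T (+ H_S/(ñP) correction); multilocus value is the
  harmonic mean with non-positive per-locus values floored at 1e−6 inside the
  mean only (raw values are still reported).
* F′ = (S̄_w − S̄_b)/(1 − S̄_b), with S̄_w the unweighted mean of the
  per-population mean pairwise Dice similarities and S̄_b the mean over all
  between-population pairs.  Two standard errors are reported: a delta-method
  propagation treating pairs as independent (an approximation — pairs share
  individuals) and a jackknife over individuals; the pipeline reports the
  delta-method SE.  Note F′ = 0 is an expectation under exchangeability, not
  an algebraic identity of small samples.
* Exact test of differentiation: Raymond–Rousset Metropolis chain over
  allele-count tables with fixed margins (default 100,000 steps after 10,000
  dememorization); p is the chain fraction of tables at most as probable as
  the observed one.  The multilocus microsatellite result combines per-locus
  p-values by Fisher's method (the alternative — one chain on pooled counts —
  is available by calling the test on the pooled table).

## Neutrality tests

* Tajima's D with the standard a₁…e₂ constants.  p-values are two-tailed
  (equal-tail doubled) from **fixed-S** simulation: genealogies from the
  neutral coalescent prior, S mutations placed multinomially by branch
  length.  This is Hudson's fixed-S scheme — it ignores tree-length
  reweighting and is therefore approximate, but its measured type-I error at
  n=30, θ=5 is 0.05.
* Fu's F_S = ln(S′/(1−S′)) with S′ = Pr(K′ ≥ K | θ̂ = k), computed from
  unsigned Stirling numbers of the first kind by the log-space recurrence
  |s(n+1,k)| = n|s(n,k)| + |s(n,k−1)| (validated against exact integers to
  n = 8); p is the lower tail over neutral simulations at θ̂.
* Ewens–Watterson–Slatkin: the observed homozygosity F = Σ(n_i/n)² is
  compared with the Ewens distribution conditional on (n, K), which is
  θ-free.  Conditional configurations are sampled exactly by the Feller
  coupling (independent Bernoulli(θ/(θ+i−1)) indicators; spacings between
  ones are the part sizes) with rejection on K, the proposal θ tuned so
  E[K] = K.  Reported: F_exp (Monte-Carlo mean), the lower homozygosity tail
  P_H (the balancing-selection side, the headline p), the upper tail, and the
  exact-style tail P_E on conditional configuration probability
  n!/(|s(n,K)|·Πn_i·Πa_j!).  For the multicopy locus the test runs on the
  count-once allele counts — an approximation, flagged in the report.

Monte-Carlo and permutation p-values throughout use the add-one convention
p = (1 + #extreme)/(reps + 1), which keeps them valid (never smaller than
1/(reps+1)) and permutation levels exact.

## Mismatch demography

The sudden-expansion model (θ₀ → θ₁ at scaled time τ = 2ut) has the exact
expected mismatch distribution

    F_s = F̂_s(θ₁)·Pr(Pois(ατ) > s) + e^(−τ/θ₁) Σ_{m≤s} Pois(m; τ)·F̂_{s−m}(θ₀)

with F̂_s(θ) = θ^s/(θ+1)^{s+1} and α = 1 + 1/θ₁ (derived by integrating the
piecewise-exponential pair-coalescence density against the Poisson mutation
kernel; it reduces to the geometric at τ=0 and to Pois(τ) as θ₀→0, θ₁→∞, and
is evaluated with stable Poisson recursions).  SSD is summed over the
observed difference classes (trailing zero classes trimmed, making the fit
invariant to zero padding).  Fitting is bounded L-BFGS-B
(τ, θ₀ ≤ 10³, θ₁ ≤ 10⁵) from a moment-based 4-point start grid; a 27-point
grid is available for one-off fits.  Raggedness follows the both-ends
zero-padded convention r = Σ(x_i − x_{i−1})² including the rise into class 0
and the fall beyond the last class.  GOF significance is a parametric
bootstrap: coalescent samples under the fitted parameters, each refit by the
same procedure (symmetry is essential — an asymmetric refit biases p).

**Known limitation.**  The bootstrap is calibrated when the data actually come
from the fitted model family's interior (measured p ≈ uniform), but at the
stationary boundary (τ = 0) it over-rejects (type-I ≈ 0.17 at nominal 0.05,
n = 30, θ = 5): stationary coalescent histograms are typically unimodal yet
over-dispersed, so least squares prefers expansion-like parameters whose
star-like genealogies yield smoother replicates.  Conditioning replicates on
the observed S does not repair this.  Single-locus mismatch GOF tests also
have low power (structured, bimodal data is rejected in well under half of
runs at n = 40) — conclusions about demography should rest on more than this
statistic.

## Genotype QC

Consensus calling is sequential over up to 7 PCRs: a heterozygote is accepted
once two alleles each have ≥2 observations (if a third singleton allele was
seen, the two confirmed alleles are reported), a homozygote after ≥3
concordant homozygous PCRs with no conflicting observation; an unresolved
stack degrades to a half-locus call when exactly one allele is confirmed,
else missing.  An allele observed once is never reported.

Error rates compare a test table against a reference over shared full
genotypes: allelic dropout is the fraction of reference-heterozygous
comparisons observed as a homozygote for a true allele; the false-allele rate
is the fraction of comparisons showing an allele absent from the reference;
the total error is the fraction of mismatching allele slots (two per
genotype) — the denominator choice is documented here because protocols
differ.

The null-allele EM apportions observed i/i homozygotes between true i/i and
i/null at HW proportions each E-step (blanks enter as null/null only when the
caller opts in; without blanks the estimate conditions on amplification and
is slightly biased, which is accepted and documented).  Convergence is
max|Δp| < 1e−8 with a boundary polish: near p_null = 0 the EM converges
sublinearly, so the boundary is accepted whenever it does not lower the
likelihood.  Bootstrap CIs resample individuals (default 10,000).

The exact HWE test shuffles gene copies into random pairings and orders
genotype arrays by conditional probability (∝ 2^H/Π n_ij!); the one-sided
variant orders by heterozygote count.  Genotypic LD uses the G statistic of
the two-locus genotype table with one locus permuted across individuals.

## Synthetic data generator

The generator's defaults are the emulated study's conditions: populations of
36 and 31 typed individuals; 13 microsatellites; intron/exon loci of 668, 246
and 205 bp with locus θ of 1.0, 2.3 and 15 (matching the observed k of
roughly 1, 2.2–2.4 and 15–20); a 14-bp intron indel; 1–4 detected alleles per
individual at the duplicated locus (detection dropout 0.35 per allele copy,
giving ≈1.6–1.8 alleles/individual); per-PCR allelic dropout 0.05 and
false-allele rate 0.01 (chosen so consensus-level totals land near the
reported sub-percent to few-percent fecal error rates); expansion scenario
τ=5, θ₀=1, θ₁=100.  Deme size N_e = 500 diploids and migration m = 0.01 per
gamete put the neutral multilocus F_ST near 0.04, the study's microsatellite
value.  These N_e/m values are desk-scale stand-ins: real effective sizes are
orders of magnitude larger, so the generator reproduces the *statistical
targets* (F_ST, θ per locus), not the real parameter values.

Engines: neutral sequence loci use msprime (2-deme island model, ploidy 2,
infinite-sites mutations on a continuous genome mapped to distinct columns of
the L-bp amplicon; a capacity error is raised if S exceeds L).  The intron
indel is one extra "mutation" dropped on the genealogy (a branch chosen
proportional to length whose descendant alleles get a contiguous deletion).
Loci under selection use a forward-time Wright–Fisher island model with
viability selection (heterozygote 1, homozygote 1−s), infinite-alleles
mutation, and burn-in 10·N_e generations from a monomorphic start; s=0
reduces exactly to drift (verified distributionally).  The `skewed` mode is
phenomenological: it pins the top allele of one deme at a target frequency
(default 0.44, the emulated predominant-allele pattern) by resampling that
deme's gene copies — no mechanistic claim.  Microsatellite loci inherit
parents independently per locus (marginally exact per-locus WF dynamics;
cross-locus identity disequilibrium is not modeled, consistent with the
multilocus estimators' independence assumptions).  The multicopy locus pairs
two diploid "gene copies" drawn from one shared coalescent allele pool and
thins each of the four allele copies with the detection-dropout probability;
an individual with nothing detected is missing.  The PCR error model drops
each true allele of a heterozygote independently per PCR (a PCR with both
alleles dropped still amplifies one at random, so any dropout shows as a
homozygote — this makes the het-miscall probability exactly 1−(1−d)²), and
substitutes a random wrong allele at the false-allele rate.

What the generator does **not** emulate: linkage and identity disequilibrium,
allele-size homoplasy constraints, locus-specific amplification success,
population substructure within demes, and real mutation-rate heterogeneity.
Passing tests therefore demonstrate the *estimators'* correctness and the
qualitative selection/demography contrasts, not field realism.

## Problem sizes used in validation

Simulation-based checks run at desk scale, chosen once: calibration suites
use n ≈ 30 gene copies, θ = 5, 500–800 replicates with 199–1999-draw nulls;
the island-model check uses N_e = 500, 5 loci, 25 individuals/deme, 50
paired replicates (so the multilocus θ sampling SD ≈ 0.009 makes the 0.02
threshold decisive); the direction-of-effect contrast uses N_e = 300,
m = 0.002, infinite-alleles μ = 2.5e−3, s = 0.3, 30+30 individuals, three
neutral comparator loci and 50 paired replicates — the little-gene-flow
regime the emulated study describes, where the balancing-selection direction
(lower F′, lower E-W-S homozygosity tail at the selected locus) is asserted
marginally at the 80% level for each statistic.
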