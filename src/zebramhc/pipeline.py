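"""Orchestrated two-population contrast: QC -> diversity -> APD ->
differentiation -> neutrality -> mismatch -> group comparisons.

Every Monte-Carlo stage draws its generator from a master seed through a fixed
counter scheme (``SeedSequence((master, stage_index))``), so stages are
independently re-runnable and the full pipeline is bit-reproducible.  A stage
failure is logged and the remaining stages are still attempted.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import diversity as div
from . import differentiation as diff
from . import mismatch as mm
from . import neutrality as neut
from . import qc as qcmod
from . import stats as gstats
from .errors import ConfigurationError, ZebraMHCError
from .io import PopulationDataset, SummaryTables

#: stage order also fixes the seed-derivation counters
STAGES = (
    "qc", "diversity", "apd", "differentiation", "neutrality", "mismatch", "comparisons",
)

DEFAULT_CONFIG = {
    "seed": 1,
    "n_perm": 1000,          # permutation tests (Phi_ST, F_ST, KW)
    "n_boot": 1000,          # bootstrap replicates (F_ST CI, mismatch)
    "mc_steps": 100000,      # differentiation exact-test chain length
    "dememorization": 10000,
    "neutrality_reps": 1000,  # Tajima/Fu null simulations
    "ews_samples": 10000,     # Ewens-Watterson conditional samples
    "rarefaction": "min",     # rarefy at the smallest per-population copy count
    "alpha": 0.05,
}


@dataclass
class ContrastReport:
    tables: SummaryTables
    log: list[str] = field(default_factory=list)


def _stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed), STAGES.index(stage)))
    )


def run_contrast(
    dataset: PopulationDataset,
    config: Optional[dict] = None,
    out_dir=None,
) -> ContrastReport:
    """Run the full neutral-vs-MHC contrast on a two-population dataset."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    if not dataset.genotypes.individuals or not dataset.genotypes.loci:
        raise ConfigurationError("empty dataset: no individuals or loci")
    pops = dataset.popmap.population_names
    if len(pops) != 2:
        raise ConfigurationError("the contrast pipeline needs exactly 2 populations")
    seed = int(cfg["seed"])
    log: list[str] = [
        f"master seed {seed}",
        "replicate counts: " + ", ".join(
            f"{k}={cfg[k]}" for k in (
                "n_perm", "n_boot", "mc_steps", "dememorization",
                "neutrality_reps", "ews_samples",
            )
        ),
    ]
    tables: dict[str, pd.DataFrame] = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn(_stage_rng(seed, name))
            log.append(f"stage {name}: ok ({time.perf_counter() - t0:.2f}s)")
        except ZebraMHCError as exc:
            log.append(f"stage {name}: FAILED ({exc})")

    table = dataset.genotypes
    popmap = dataset.popmap
    msat_loci = dataset.loci_of_kind("microsatellite")
    seq_diploid = dataset.loci_of_kind("sequence_diploid")
    seq_multi = dataset.loci_of_kind("sequence_multicopy")
    seq_loci = seq_diploid + seq_multi

    # ---- QC ---------------------------------------------------------------
    def stage_qc(rng):
        rows = []
        for pop in pops:
            for locus in msat_loci:
                genos = [table.call(i, locus) for i in popmap.members(pop)]
                full = [g for g in genos if g is not None and g[1] is not None]
                if len(full) < 2 or len({a for g in full for a in g}) < 2:
                    continue
                hwe = qcmod.hwe_exact_mc(full, n_mc=min(int(cfg["n_perm"]), 10000), rng=rng)
                counts = {}
                for g in full:
                    counts[g] = counts.get(g, 0) + 1
                counts[None] = sum(1 for g in genos if g is None)
                try:
                    em = qcmod.null_allele_em(counts)
                    naf = em.naf
                except ZebraMHCError:
                    naf = math.nan
                rows.append(
                    {"population": pop, "locus": locus, "hwe_p": hwe.p,
                     "hwe_het_deficiency_p": hwe.p_het_deficiency, "naf": naf}
                )
        if rows:
            tables["qc"] = pd.DataFrame(rows)

    # ---- diversity --------------------------------------------------------
    def stage_diversity(rng):
        rows = []
        for locus in msat_loci + seq_loci:
            kind = table.loci[locus]
            mode = "multicopy" if kind == "sequence_multicopy" else "diploid"
            spectra = {
                p: div.allele_frequencies(table, popmap, locus, p, mode=mode) for p in pops
            }
            g_min = min(s.n for s in spectra.values())
            for pop in pops:
                spec = spectra[pop]
                if spec.n < 2:
                    continue
                het = div.heterozygosity(spec, table, popmap)
                n_ind = sum(
                    1 for i in popmap.members(pop) if table.call(i, locus) is not None
                )
                row = {
                    "population": pop, "locus": locus, "N": n_ind,
                    "A": spec.n_alleles,
                    "A_corr": div.allelic_richness_rarefied(spec, g_min),
                    "H_E": het.h_exp_unbiased, "H_O": het.h_obs,
                    "S": None, "indel_bp": None, "k": None,
                    "H_D": None, "H_D_sd": None, "pi": None, "pi_sd": None,
                }
                if kind == "sequence_diploid" and locus in dataset.alignments:
                    copies = div.gene_copies(table, popmap, locus, pop)
                    if len(copies) >= 2:
                        st = div.seq_diversity_stats(dataset.alignments[locus], copies)
                        row.update(
                            S=st.S, indel_bp=st.indel_bp, k=st.k, H_D=st.hd,
                            H_D_sd=st.hd_sd, pi=st.pi, pi_sd=st.pi_sd,
                        )
                elif kind == "sequence_multicopy" and locus in dataset.alignments:
                    # gene copies approximated by the count-once convention
                    copies = [
                        a for ind in popmap.members(pop)
                        for a in (table.call(ind, locus) or ())
                    ]
                    if len(copies) >= 2:
                        st = div.seq_diversity_stats(dataset.alignments[locus], copies)
                        row.update(
                            S=st.S, indel_bp=st.indel_bp, k=st.k, H_D=st.hd,
                            H_D_sd=st.hd_sd, pi=st.pi, pi_sd=st.pi_sd,
                        )
                rows.append(row)
        tables["diversity"] = pd.DataFrame(rows)

    # ---- APD --------------------------------------------------------------
    def stage_apd(rng):
        rows = []
        for locus in seq_loci:
            for pop in pops:
                try:
                    r = div.apd(table, popmap, locus, pop)
                except ZebraMHCError:
                    continue
                rows.append(
                    {"population": pop, "locus": locus, "C": r.C,
                     "APD": r.apd, "SE": r.se}
                )
        if rows:
            tables["apd"] = pd.DataFrame(rows)

    # ---- differentiation --------------------------------------------------
    def stage_differentiation(rng):
        rows = []
        if msat_loci:
            wc = diff.wc_fst(
                table, popmap, loci=msat_loci,
                n_boot=int(cfg["n_boot"]), n_perm=int(cfg["n_perm"]), rng=rng,
            )
            dests = []
            for locus in msat_loci:
                spectra = [
                    div.allele_frequencies(table, popmap, locus, p) for p in pops
                ]
                try:
                    dests.append(diff.jost_dest(spectra))
                except ZebraMHCError:
                    dests.append(math.nan)
                counts_tab = _count_table(spectra)
                p_exact = diff.exact_test_differentiation(
                    counts_tab, mc_steps=int(cfg["mc_steps"]),
                    dememorization=int(cfg["dememorization"]), rng=rng,
                )
                rows.append(
                    {"locus": locus, "F_ST": wc.per_locus.get(locus),
                     "F_ST_p": wc.p_per_locus.get(locus), "Phi_ST": None,
                     "Phi_ST_p": None, "exact_p": p_exact, "F_prime": None,
                     "F_prime_se": None, "D_est": dests[-1]}
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d_multi = diff.jost_dest_multilocus(dests)
            rows.append(
                {"locus": "msat_multilocus", "F_ST": wc.multilocus,
                 "F_ST_p": wc.p_multilocus, "Phi_ST": None, "Phi_ST_p": None,
                 "exact_p": diff.fisher_combined_p(
                     [r["exact_p"] for r in rows if r["locus"] in msat_loci]
                 ),
                 "F_prime": None, "F_prime_se": None, "D_est": d_multi,
                 "F_ST_ci_low": wc.ci_low, "F_ST_ci_high": wc.ci_high}
            )
        for locus in seq_loci:
            kind = table.loci[locus]
            mode = "multicopy" if kind == "sequence_multicopy" else "diploid"
            spectra = [
                div.allele_frequencies(table, popmap, locus, p, mode=mode) for p in pops
            ]
            fst = diff.haplotype_fst_from_spectra(spectra)
            aln = dataset.alignments.get(locus)
            phi = phi_p = None
            fst_p = None
            try:
                am_id = diff.phi_st_amova(
                    aln, table, popmap, locus, distance="identity",
                    n_perm=int(cfg["n_perm"]), rng=rng,
                )
                fst_p = am_id.p
            except ZebraMHCError:
                pass
            if aln is not None:
                try:
                    am = diff.phi_st_amova(
                        aln, table, popmap, locus, distance="k2p",
                        n_perm=int(cfg["n_perm"]), rng=rng,
                    )
                    phi, phi_p = am.phi_st, am.p
                except ZebraMHCError:
                    pass
            try:
                fp = diff.f_prime(table, popmap, locus)
                fpv, fpse = fp.f_prime, fp.se_delta
            except ZebraMHCError:
                fpv = fpse = None
            try:
                dest = diff.jost_dest(spectra)
            except ZebraMHCError:
                dest = math.nan
            p_exact = diff.exact_test_differentiation(
                _count_table(spectra), mc_steps=int(cfg["mc_steps"]),
                dememorization=int(cfg["dememorization"]), rng=rng,
            )
            rows.append(
                {"locus": locus, "F_ST": fst, "F_ST_p": fst_p, "Phi_ST": phi,
                 "Phi_ST_p": phi_p, "exact_p": p_exact, "F_prime": fpv,
                 "F_prime_se": fpse, "D_est": dest}
            )
        tables["differentiation"] = pd.DataFrame(rows)

    # ---- neutrality -------------------------------------------------------
    def stage_neutrality(rng):
        rows = []
        reps = int(cfg["neutrality_reps"])
        for locus in seq_loci:
            kind = table.loci[locus]
            aln = dataset.alignments.get(locus)
            for pop in pops:
                if kind == "sequence_multicopy":
                    # approximate gene copies via the count-once convention
                    spec = div.allele_frequencies(table, popmap, locus, pop, mode="multicopy")
                    config_counts = list(spec.counts.values())
                    copies = [
                        a for ind in popmap.members(pop)
                        for a in (table.call(ind, locus) or ())
                    ]
                else:
                    copies = div.gene_copies(table, popmap, locus, pop)
                    config_counts = list(
                        div.AlleleFrequencySpectrum(
                            locus, pop,
                            dict(zip(*np.unique(copies, return_counts=True))),
                        ).counts.values()
                    ) if copies else []
                if len(copies) < 4 or aln is None:
                    continue
                st = div.seq_diversity_stats(aln, copies)
                n = len(copies)
                row = {"population": pop, "locus": locus, "n": n,
                       "D": None, "D_p": None, "F_S": None, "F_S_p": None,
                       "F_obs": None, "F_exp": None, "P_H": None, "P_E": None}
                if st.S >= 1:
                    d = neut.tajimas_d(st.S, st.k, n)
                    row["D"] = d
                    row["D_p"] = neut.tajimas_d_pvalue(d, n, st.S, n_reps=reps, rng=rng)
                ews_config = neut.AlleleConfiguration(
                    [int(c) for c in config_counts]
                ) if config_counts else None
                if ews_config is not None and ews_config.K >= 2 and st.k > 0:
                    row["F_S"] = neut.fus_fs(ews_config.K, st.k, ews_config.n)
                    row["F_S_p"] = neut.fus_fs_pvalue(
                        row["F_S"], ews_config.n, st.k, n_reps=max(reps // 5, 100), rng=rng
                    )
                if ews_config is not None:
                    ews = neut.ewens_watterson_slatkin(
                        ews_config, n_mc=int(cfg["ews_samples"]), rng=rng
                    )
                    row.update(F_obs=ews.f_obs, F_exp=ews.f_exp,
                               P_H=ews.p_h, P_E=ews.p_e)
                rows.append(row)
        tables["neutrality"] = pd.DataFrame(rows)

    # ---- mismatch ---------------------------------------------------------
    def stage_mismatch(rng):
        rows = []
        for locus in seq_diploid:
            aln = dataset.alignments.get(locus)
            if aln is None:
                continue
            for pop in pops:
                copies = div.gene_copies(table, popmap, locus, pop)
                if len(copies) < 3:
                    continue
                res = mm.mismatch_analysis(
                    aln, copies, n_boot=int(cfg["n_boot"]), rng=rng
                )
                rows.append(
                    {"population": pop, "locus": locus,
                     "tau": res.fit.tau, "theta0": res.fit.theta0,
                     "theta1": res.fit.theta1, "SSD": res.fit.ssd,
                     "SSD_p": res.p_ssd, "raggedness": res.r, "raggedness_p": res.p_r}
                )
        if rows:
            tables["mismatch"] = pd.DataFrame(rows)

    # ---- group comparisons ------------------------------------------------
    def stage_comparisons(rng):
        rows = []
        for locus in seq_loci:
            try:
                pair_vals, pair_labels = [], []
                for pop in pops:
                    r = div.apd(table, popmap, locus, pop)
                    pair_vals.extend(r.pair_values)
                    pair_labels.extend([pop] * len(r.pair_values))
                kw = gstats.kruskal_wallis_randomization(
                    pair_vals, pair_labels, n_perm=int(cfg["n_perm"]), rng=rng
                )
                wz = gstats.wilcoxon_ranksum_z(pair_vals, pair_labels)
                lv = gstats.levene_test(pair_vals, pair_labels)
                rows.append({"locus": locus, "test": "KW_APD", "value": kw.value,
                             "p": kw.p, "method": kw.method})
                rows.append({"locus": locus, "test": "Wilcoxon_APD", "value": wz.value,
                             "p": wz.p, "method": wz.method})
                rows.append({"locus": locus, "test": "Levene_APD", "value": lv.value,
                             "p": lv.p, "method": lv.method})
            except ZebraMHCError:
                pass
        for locus in seq_loci + msat_loci:
            kind = table.loci[locus]
            mode = "multicopy" if kind == "sequence_multicopy" else "diploid"
            spectra = [
                div.allele_frequencies(table, popmap, locus, p, mode=mode) for p in pops
            ]
            tab = _count_table(spectra)
            if tab.shape[0] < 2:
                continue
            cs = gstats.chisq_contingency(tab.T)
            rows.append({"locus": locus, "test": "ChiSq_freqs", "value": cs.value,
                         "p": cs.p, "method": cs.method})
        df = pd.DataFrame(rows)
        if len(df):
            adj, reject = gstats.holm_correction(df["p"].to_numpy(), alpha=cfg["alpha"])
            df["p_holm"] = adj
            df["reject_holm"] = reject
        tables["comparisons"] = df

    run_stage("qc", stage_qc)
    run_stage("diversity", stage_diversity)
    run_stage("apd", stage_apd)
    run_stage("differentiation", stage_differentiation)
    run_stage("neutrality", stage_neutrality)
    run_stage("mismatch", stage_mismatch)
    run_stage("comparisons", stage_comparisons)

    summary = SummaryTables(tables)
    if out_dir is not None:
        summary.write(out_dir)
        log.append(f"tables written to {out_dir}")
    return ContrastReport(tables=summary, log=log)


def _count_table(spectra) -> np.ndarray:
    """Alleles x populations count table from per-population spectra."""
    alleles = sorted({a for s in spectra for a in s.counts})
    return np.array(
        [[s.counts.get(a, 0) for s in spectra] for a in alleles], dtype=int
    )
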