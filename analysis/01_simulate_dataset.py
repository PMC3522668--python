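#!/usr/bin/env python
"""Generate the synthetic two-population study dataset.

Emulates the field design: two park populations (36 and 31 typed individuals),
13 stepwise microsatellites, a 668-bp neutral intron with a 14-bp indel
polymorphism, a 246-bp single-copy MHC exon under overdominant selection, and
a 205-bp possibly duplicated MHC locus with 1-4 detected alleles per
individual.  Writes the dataset directory plus replicate-PCR call tables for
the genotyping-QC stage.
"""

import sys
from pathlib import Path

import pandas as pd

from zebramhc import io as zio
from zebramhc.cli import build_dataset
from zebramhc.simulate import SimScenario, generate_pcr_replicates

OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    scenario = SimScenario(seed=SEED)
    dataset = build_dataset(scenario)
    zio.write_dataset(dataset, OUT)

    # replicate-PCR tables for the microsatellites (fecal-DNA error model)
    rng = scenario.rng(7)
    msat_only = zio.GenotypeTable(
        individuals=list(dataset.genotypes.individuals),
        loci={l: k for l, k in dataset.genotypes.loci.items() if k == "microsatellite"},
    )
    for (ind, locus), call in dataset.genotypes.calls.items():
        if locus in msat_only.loci:
            msat_only.calls[(ind, locus)] = call
    reps = generate_pcr_replicates(
        msat_only, scenario.pcr_dropout, scenario.pcr_false, scenario.n_pcr, rng=rng
    )
    rows = []
    for r, rep in enumerate(reps, start=1):
        for ind in rep.individuals:
            for locus in rep.loci:
                call = rep.call(ind, locus)
                rows.append(
                    {"individual": ind, "locus": locus, "pcr_index": r,
                     "allele1": "NA" if call is None else call[0],
                     "allele2": "NA" if call is None or call[1] is None else call[1]}
                )
    pd.DataFrame(rows).to_csv(OUT / "replicates.tsv", sep="\t", index=False)

    n_pop = {p: len(dataset.popmap.members(p)) for p in dataset.popmap.population_names}
    print(f"dataset written to {OUT}")
    print(f"individuals per population: {n_pop}")
    print(f"loci: {list(dataset.genotypes.loci)}")


if __name__ == "__main__":
    main()
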