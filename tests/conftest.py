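import numpy as np
import pytest

from zebramhc.io import GenotypeTable, LocusAlignment, PopulationMap


@pytest.fixture
def rng():
    return np.random.default_rng(8675309)


@pytest.fixture
def tiny_alignment():
    """Four 12-bp haplotypes, two indel columns (3 and 4), a few substitutions."""
    return LocusAlignment(
        locus_id="toy",
        allele_ids=["h1", "h2", "h3", "h4"],
        sequences=[
            "ACGTACGTACGT",
            "ACG--CGTACGT",
            "ACGTACGTACGA",
            "ACGTACATACGA",
        ],
    )


def make_diploid_table(calls_by_pop, locus="L", kind="sequence_diploid"):
    """calls_by_pop: {pop: [call, ...]} -> (GenotypeTable, PopulationMap)."""
    individuals, assignments = [], {}
    table = GenotypeTable(individuals=[], loci={locus: kind})
    for pop, calls in calls_by_pop.items():
        for i, call in enumerate(calls):
            name = f"{pop}_{i}"
            individuals.append(name)
            assignments[name] = pop
            table.calls[(name, locus)] = call
    table.individuals = individuals
    return table, PopulationMap(assignments)
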