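"""Data model and readers/writers for alignments, genotype tables and result tables.

The in-memory containers here are the unit every analysis module consumes:

* :class:`LocusAlignment` — aligned haplotype ("allele") sequences for one locus,
  with indel-column bookkeeping.  All pairwise sequence statistics in the package
  use complete deletion of indel columns, so the alignment exposes
  ``analyzed_sites = alignment_length - len(indel_columns)``.
* :class:`GenotypeTable` — individuals x loci calls.  Microsatellite and
  single-copy sequence loci carry diploid allele pairs (order-free); a possibly
  duplicated locus carries a set of 1–4 distinct allele IDs; half-locus calls
  (one scored allele, the other missing) and fully missing calls are preserved.
* :class:`PopulationMap` — individual -> population label.
* :class:`PopulationDataset` — the bundle of genotypes, alignments and map.
* :class:`SummaryTables` — the per-locus/per-population result tables, written
  as one TSV per table.

File formats are deliberately plain: FASTA for alignments (via Biopython) and
TSV for everything else.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    ConfigurationError,
    CrossReferenceError,
    DataError,
    FormatError,
)

MISSING_CODE = "NA"

LOCUS_KINDS = ("microsatellite", "sequence_diploid", "sequence_multicopy")

#: call types, by locus kind:
#:   microsatellite / sequence_diploid: tuple (a, b); half-locus (a, None); None
#:   sequence_multicopy: tuple of 1-4 distinct allele ids (sorted); None
Call = Optional[tuple]


@dataclass
class LocusAlignment:
    """Aligned haplotype sequences for one locus."""

    locus_id: str
    allele_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.allele_ids) != len(self.sequences):
            raise AlignmentError("allele_ids and sequences differ in length")
        if not self.sequences:
            raise AlignmentError(f"{self.locus_id}: empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_id}: ragged sequence lengths {sorted(lengths)}"
            )
        if len(set(self.allele_ids)) != len(self.allele_ids):
            raise FormatError(f"{self.locus_id}: duplicate allele IDs")
        self.sequences = [s.upper() for s in self.sequences]
        self._index = {a: i for i, a in enumerate(self.allele_ids)}

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0])

    @property
    def indel_columns(self) -> frozenset[int]:
        """Columns where any haplotype carries a gap ('-')."""
        cols = set()
        for seq in self.sequences:
            cols.update(i for i, c in enumerate(seq) if c == "-")
        return frozenset(cols)

    @property
    def analyzed_sites(self) -> int:
        return self.alignment_length - len(self.indel_columns)

    def sequence(self, allele_id: str) -> str:
        try:
            return self.sequences[self._index[allele_id]]
        except KeyError:
            raise CrossReferenceError(
                f"{self.locus_id}: unknown allele {allele_id!r}"
            ) from None

    def __contains__(self, allele_id: str) -> bool:
        return allele_id in self._index

    @classmethod
    def from_fasta(cls, path, locus_id: str) -> "LocusAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise FormatError(f"{path}: no FASTA records")
        return cls(
            locus_id=locus_id,
            allele_ids=[r.id for r in records],
            sequences=[str(r.seq) for r in records],
        )

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=a, description="")
            for a, s in zip(self.allele_ids, self.sequences)
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")


@dataclass
class GenotypeTable:
    """Individuals x loci genotype calls."""

    individuals: list[str]
    loci: dict[str, str]  # locus_id -> kind
    calls: dict[tuple[str, str], Call] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, kind in self.loci.items():
            if kind not in LOCUS_KINDS:
                raise DataError(f"{locus}: unknown locus kind {kind!r}")

    def call(self, individual: str, locus: str) -> Call:
        return self.calls.get((individual, locus))

    def set_call(self, individual: str, locus: str, call: Call) -> None:
        kind = self.loci[locus]
        self.calls[(individual, locus)] = _normalize_call(call, kind)

    def alleles_of(self, individual: str, locus: str) -> tuple:
        """Scored alleles of a call (drops the missing half of half-locus calls)."""
        call = self.call(individual, locus)
        if call is None:
            return ()
        return tuple(a for a in call if a is not None)

    def validate_against(self, alignments: Mapping[str, LocusAlignment]) -> None:
        for (ind, locus), call in self.calls.items():
            if call is None or locus not in alignments:
                continue
            aln = alignments[locus]
            for allele in call:
                if allele is not None and allele not in aln:
                    raise CrossReferenceError(
                        f"{ind}/{locus}: allele {allele!r} not in alignment"
                    )

    # -- TSV round trip -----------------------------------------------------

    @classmethod
    def from_tsv(
        cls,
        path,
        schema: Mapping[str, str],
        missing_code: str = MISSING_CODE,
    ) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna(missing_code)
        if "individual" not in df.columns:
            raise FormatError(f"{path}: missing 'individual' column")
        table = cls(individuals=list(df["individual"]), loci=dict(schema))
        for locus in schema:
            if locus not in df.columns:
                raise FormatError(f"{path}: missing locus column {locus!r}")
        for _, row in df.iterrows():
            ind = row["individual"]
            for locus, kind in schema.items():
                table.calls[(ind, locus)] = parse_call(
                    row[locus], kind, missing_code=missing_code
                )
        return table

    def to_tsv(self, path, missing_code: str = MISSING_CODE) -> None:
        rows = []
        for ind in self.individuals:
            row = {"individual": ind}
            for locus, kind in self.loci.items():
                row[locus] = format_call(
                    self.call(ind, locus), kind, missing_code=missing_code
                )
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _normalize_call(call: Call, kind: str) -> Call:
    if call is None:
        return None
    if kind == "sequence_multicopy":
        alleles = tuple(sorted(set(call)))
        if not 1 <= len(alleles) <= 4:
            raise DataError(f"multicopy call must have 1-4 alleles: {call!r}")
        return alleles
    if len(call) != 2:
        raise DataError(f"diploid call must be a pair: {call!r}")
    a, b = call
    if a is None and b is None:
        return None
    if a is None:
        a, b = b, a
    if b is None:
        return (a, None)
    return tuple(sorted((a, b)))


def parse_call(cell: str, kind: str, missing_code: str = MISSING_CODE) -> Call:
    cell = cell.strip()
    if not cell or cell == missing_code:
        return None
    if kind == "sequence_multicopy":
        alleles = tuple(sorted({a.strip() for a in cell.split(",") if a.strip()}))
        if len(alleles) > 4:
            raise DataError(f"multicopy cell with >4 alleles: {cell!r}")
        return alleles if alleles else None
    parts = cell.split("/")
    if len(parts) != 2:
        raise FormatError(f"diploid cell must be 'a/b': {cell!r}")
    a = None if parts[0] == missing_code else parts[0]
    b = None if parts[1] == missing_code else parts[1]
    return _normalize_call((a, b), kind)


def format_call(call: Call, kind: str, missing_code: str = MISSING_CODE) -> str:
    if call is None:
        return missing_code
    if kind == "sequence_multicopy":
        return ",".join(call)
    a, b = call
    return f"{a}/{b if b is not None else missing_code}"


@dataclass
class PopulationMap:
    """Individual -> population label."""

    assignments: dict[str, str]

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop)
        return list(seen)

    def members(self, population: str) -> list[str]:
        return [i for i, p in self.assignments.items() if p == population]

    def population_of(self, individual: str) -> str:
        return self.assignments[individual]

    def validate_covers(self, table: GenotypeTable) -> None:
        missing = [i for i in table.individuals if i not in self.assignments]
        if missing:
            raise ConfigurationError(f"individuals without population: {missing[:5]}")
        for pop in self.population_names:
            if not self.members(pop):
                raise ConfigurationError(f"empty population {pop!r}")

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"individual", "population"} <= set(df.columns):
            raise FormatError(f"{path}: need columns individual, population")
        return cls(dict(zip(df["individual"], df["population"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"individual": list(self.assignments), "population": list(self.assignments.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class PopulationDataset:
    """Everything the analyses consume for one study."""

    genotypes: GenotypeTable
    popmap: PopulationMap
    alignments: dict[str, LocusAlignment] = field(default_factory=dict)
    replicate_calls: Optional[pd.DataFrame] = None  # long format PCR replicates

    def __post_init__(self) -> None:
        self.popmap.validate_covers(self.genotypes)
        self.genotypes.validate_against(self.alignments)

    def loci_of_kind(self, kind: str) -> list[str]:
        return [l for l, k in self.genotypes.loci.items() if k == kind]


TABLE_NAMES = ("diversity", "apd", "differentiation", "neutrality", "mismatch", "comparisons")


@dataclass
class SummaryTables:
    """Per-locus/per-population result tables (one DataFrame per report)."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in sorted(self.tables):
            path = out_dir / f"{name}.tsv"
            self.tables[name].to_csv(path, sep="\t", index=False, float_format="%.6f")
            written.append(path)
        return written

    @classmethod
    def read(cls, out_dir) -> "SummaryTables":
        out_dir = Path(out_dir)
        tables = {
            p.stem: pd.read_csv(p, sep="\t") for p in sorted(out_dir.glob("*.tsv"))
        }
        return cls(tables)


# -- dataset directory layout ----------------------------------------------

def write_dataset(dataset: PopulationDataset, out_dir) -> None:
    """Write a dataset as genotypes.tsv / popmap.tsv / loci.tsv / alignments/*.fasta."""
    out_dir = Path(out_dir)
    (out_dir / "alignments").mkdir(parents=True, exist_ok=True)
    dataset.genotypes.to_tsv(out_dir / "genotypes.tsv")
    dataset.popmap.to_tsv(out_dir / "popmap.tsv")
    pd.DataFrame(
        {"locus": list(dataset.genotypes.loci), "kind": list(dataset.genotypes.loci.values())}
    ).to_csv(out_dir / "loci.tsv", sep="\t", index=False)
    for locus, aln in dataset.alignments.items():
        aln.to_fasta(out_dir / "alignments" / f"{locus}.fasta")
    if dataset.replicate_calls is not None:
        dataset.replicate_calls.to_csv(out_dir / "replicates.tsv", sep="\t", index=False)


def read_dataset(in_dir) -> PopulationDataset:
    in_dir = Path(in_dir)
    loci_df = pd.read_csv(in_dir / "loci.tsv", sep="\t", dtype=str)
    schema = dict(zip(loci_df["locus"], loci_df["kind"]))
    genotypes = GenotypeTable.from_tsv(in_dir / "genotypes.tsv", schema)
    popmap = PopulationMap.from_tsv(in_dir / "popmap.tsv")
    alignments = {}
    for fasta in sorted((in_dir / "alignments").glob("*.fasta")):
        alignments[fasta.stem] = LocusAlignment.from_fasta(fasta, fasta.stem)
    replicates = None
    rep_path = in_dir / "replicates.tsv"
    if rep_path.exists():
        replicates = pd.read_csv(rep_path, sep="\t", dtype=str)
    return PopulationDataset(
        genotypes=genotypes, popmap=popmap, alignments=alignments, replicate_calls=replicates
    )


def load_config(path) -> dict:
    """Load the nested key-value run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg
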