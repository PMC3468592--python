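"""Core domain objects for a multi-locus NGS dataset.

The central abstraction is a :class:`Dataset` linking three ingredients of a
genome-enrichment study (RAD-seq, amplicon, sequence capture):

* demographic records — one :class:`Individual` per sequenced sample, each
  assigned to a population;
* called loci — one :class:`Locus` per genomic region, holding the aligned
  phased alleles (:class:`AlleleSequence`) produced by a genotype caller;
* read alignments — one :class:`AlignmentIndex` per individual, grouping the
  primary alignment records from that individual's BAM/SAM file under the
  locus reference each read maps to.

Loci and alignments are linked by name: a locus's name must equal the
reference-sequence name its reads were aligned to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

__all__ = [
    "Individual",
    "AlleleSequence",
    "Locus",
    "ReadRecord",
    "AlignmentIndex",
    "Dataset",
]

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn-",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn-",
)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC codes and gaps handled)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Individual:
    """One sequenced sample: unique id, population of origin, and any
    free-form demographic columns (locality, sex, ...) in file order."""

    id: str
    population: str
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Individual id must be non-empty")
        if not self.population:
            raise ValueError(f"Individual {self.id!r}: population must be non-empty")


@dataclass(frozen=True)
class AlleleSequence:
    """One phased allele of one individual at one locus."""

    individual_id: str
    allele_index: int
    sequence: str

    def __post_init__(self) -> None:
        if self.allele_index < 0:
            raise ValueError("allele_index must be >= 0")
        if not self.sequence:
            raise ValueError(
                f"empty sequence for {self.individual_id}_{self.allele_index}"
            )


@dataclass(frozen=True)
class Locus:
    """One called locus: an aligned set of phased alleles.

    All alleles share the alignment length; ``length`` is the number of
    alignment columns.
    """

    name: str
    alleles: tuple[AlleleSequence, ...]
    length: int

    def __post_init__(self) -> None:
        for a in self.alleles:
            if len(a.sequence) != self.length:
                raise ValueError(
                    f"locus {self.name!r}: allele {a.individual_id}_{a.allele_index} "
                    f"has length {len(a.sequence)}, expected {self.length}"
                )

    @property
    def individual_ids(self) -> set[str]:
        """Distinct individuals carrying at least one allele at this locus."""
        return {a.individual_id for a in self.alleles}


@dataclass(frozen=True)
class ReadRecord:
    """One primary sequencing read as stored in the alignment file.

    ``sequence`` is the SEQ field (reference orientation for mapped reads);
    ``is_reverse`` records the strand flag so the original sequencer
    orientation can be recovered. ``locus_name`` is None for unmapped reads.
    """

    read_id: str
    sequence: str
    individual_id: str
    locus_name: Optional[str]
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")

    def original_orientation_sequence(self) -> str:
        """The read as the sequencer emitted it (reverse-complemented back
        when the aligner flipped it onto the reverse strand)."""
        return reverse_complement(self.sequence) if self.is_reverse else self.sequence


@dataclass
class AlignmentIndex:
    """Per-individual read tallies and retrievable reads, grouped by the
    locus reference they map to.

    ``total_reads`` counts every primary record once (mapped or unmapped);
    ``used_reads`` counts the mapped primaries.
    """

    individual_id: str
    reads_by_locus: Dict[str, List[ReadRecord]] = field(default_factory=dict)
    unmapped: List[ReadRecord] = field(default_factory=list)

    @property
    def used_reads(self) -> int:
        return sum(len(v) for v in self.reads_by_locus.values())

    @property
    def total_reads(self) -> int:
        return self.used_reads + len(self.unmapped)

    def count(self, locus_name: str) -> int:
        return len(self.reads_by_locus.get(locus_name, []))


@dataclass
class Dataset:
    """The linked collation of individuals, loci and alignments.

    Built by :func:`locusqc.ingest.build_dataset`, which enforces referential
    closure: every allele's owner and every alignment's individual exists in
    ``individuals``, and every individual has an :class:`AlignmentIndex`
    (possibly empty).
    """

    individuals: Dict[str, Individual]
    loci: Dict[str, Locus]
    alignments: Dict[str, AlignmentIndex]
    # demographic-file order of individuals, preserved for reports
    individual_order: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.individual_order:
            self.individual_order = list(self.individuals)

    def populations(self) -> List[str]:
        """Distinct population names in first-appearance order."""
        seen: Dict[str, None] = {}
        for iid in self.individual_order:
            seen.setdefault(self.individuals[iid].population, None)
        return list(seen)

    def members_of(self, population: str) -> List[str]:
        return [
            iid
            for iid in self.individual_order
            if self.individuals[iid].population == population
        ]
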