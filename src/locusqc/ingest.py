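"""Loaders for the three input categories and the dataset assembler.

Inputs
------
* demographic TSV — header row, column 1 = individual id, column 2 =
  population, further columns preserved verbatim;
* locus FASTA files — one aligned multi-FASTA per locus, record headers
  encoding individual id and allele index (default ``>IND_0`` / ``>IND_1``,
  the last underscore splitting off the allele index);
* one SAM/BAM per individual — BAM must be coordinate-sorted and indexed;
  the reference-sequence names are the locus names.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pysam
from Bio import SeqIO

from .model import (
    AlignmentIndex,
    AlleleSequence,
    Dataset,
    Individual,
    Locus,
    ReadRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Default FASTA header convention: everything before the last underscore is
#: the individual id, the trailing integer is the allele index.
DEFAULT_HEADER_PATTERN = r"^(?P<individual>.+)_(?P<allele>\d+)$"


class IngestError(ValueError):
    """Hard error while loading or cross-validating inputs."""


def load_demographics(path: PathLike, *, delimiter: str = "\t") -> List[Individual]:
    """Parse the demographic table into :class:`Individual` records.

    The first row is a header; the first column is the individual id and the
    second its population. Any further columns are kept, in file order, in
    ``Individual.extra``. Population is required on every row (use a sentinel
    such as ``NA`` when genuinely unknown).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    if not rows:
        raise IngestError(f"demographic file {path} is empty")
    header = [c.strip() for c in rows[0]]
    if len(header) < 2:
        raise IngestError(
            f"demographic file {path} needs at least two columns "
            "(individual, population)"
        )
    extra_cols = header[2:]
    individuals: List[Individual] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        cells = [c.strip() for c in row]
        iid = cells[0] if cells else ""
        if not iid:
            raise IngestError(f"{path}:{lineno}: empty individual id")
        if iid in seen:
            raise IngestError(f"{path}:{lineno}: duplicate individual id {iid!r}")
        seen.add(iid)
        pop = cells[1] if len(cells) > 1 else ""
        if not pop:
            raise IngestError(
                f"{path}:{lineno}: individual {iid!r} has no population "
                "(population is required; use a sentinel like 'NA' if unknown)"
            )
        extra = {
            col: (cells[2 + i] if 2 + i < len(cells) else "")
            for i, col in enumerate(extra_cols)
        }
        individuals.append(Individual(id=iid, population=pop, extra=extra))
    return individuals


def _parse_header(header: str, pattern: re.Pattern[str], path: Path) -> tuple[str, int, Optional[str]]:
    m = pattern.match(header)
    if not m:
        raise IngestError(
            f"{path}: FASTA header {header!r} does not match the locus header "
            f"pattern {pattern.pattern!r}"
        )
    groups = m.groupdict()
    locus = groups.get("locus")
    return groups["individual"], int(groups["allele"]), locus


def load_loci(
    paths: Iterable[PathLike],
    *,
    header_pattern: str = DEFAULT_HEADER_PATTERN,
) -> List[Locus]:
    """Parse one aligned multi-FASTA per locus into :class:`Locus` objects.

    The locus name is the file stem unless ``header_pattern`` captures a
    ``locus`` group. ``header_pattern`` must capture named groups
    ``individual`` and ``allele``. Sequences are upper-cased on ingest.
    Files with no records are skipped with a warning; unequal sequence
    lengths within one file are a hard error.
    """
    pattern = re.compile(header_pattern)
    if not {"individual", "allele"} <= set(pattern.groupindex):
        raise IngestError(
            "header_pattern must define named groups 'individual' and 'allele'"
        )
    loci: List[Locus] = []
    for raw in paths:
        path = Path(raw)
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            logger.warning("skipping empty FASTA %s", path)
            continue
        name = path.stem
        alleles: List[AlleleSequence] = []
        for rec in records:
            iid, allele_idx, locus_group = _parse_header(rec.id, pattern, path)
            if locus_group:
                name = locus_group
            alleles.append(
                AlleleSequence(
                    individual_id=iid,
                    allele_index=allele_idx,
                    sequence=str(rec.seq).upper(),
                )
            )
        lengths = {len(a.sequence) for a in alleles}
        if len(lengths) != 1:
            raise IngestError(
                f"locus {name!r} ({path}): sequences are not aligned — "
                f"lengths {sorted(lengths)}"
            )
        loci.append(Locus(name=name, alleles=tuple(alleles), length=lengths.pop()))
    return loci


def _is_primary(read: pysam.AlignedSegment) -> bool:
    return not (read.is_secondary or read.is_supplementary)


def load_alignments(
    bam_paths: Iterable[PathLike],
    sample_map: Optional[Mapping[PathLike, str]] = None,
) -> List[AlignmentIndex]:
    """Read per-individual SAM/BAM files into :class:`AlignmentIndex` objects.

    ``sample_map`` maps each path to its individual id; by default the file
    stem is the individual id. Only primary records are counted — secondary
    and supplementary alignments are skipped, so a read pair contributes two
    reads (one per primary record). ``total_reads`` therefore requires
    unmapped reads to have been kept in the BAM; a BAM stripped of unmapped
    records will report ``total_reads == used_reads``.

    BAM files must be coordinate-sorted and indexed (``samtools sort``/
    ``samtools index``); plain SAM text is accepted as-is.
    """
    resolved: Dict[Path, str] = {}
    if sample_map is not None:
        resolved = {Path(k): v for k, v in sample_map.items()}
    indexes: List[AlignmentIndex] = []
    for raw in bam_paths:
        path = Path(raw)
        if not path.exists():
            raise IngestError(f"alignment file {path} does not exist")
        if sample_map is not None and path not in resolved:
            raise IngestError(f"{path} is missing from the sample map")
        iid = resolved.get(path, path.stem)
        is_bam = path.suffix.lower() == ".bam"
        mode = "rb" if is_bam else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
            if is_bam and not af.has_index():
                raise IngestError(
                    f"{path} has no index; sort and index it first "
                    "(samtools sort / samtools index)"
                )
            idx = AlignmentIndex(individual_id=iid)
            for read in af.fetch(until_eof=True):
                if not _is_primary(read):
                    continue
                rec = ReadRecord(
                    read_id=read.query_name,
                    sequence=(read.query_sequence or "").upper(),
                    individual_id=iid,
                    locus_name=None if read.is_unmapped else read.reference_name,
                    is_reverse=bool(read.is_reverse) and not read.is_unmapped,
                )
                if rec.locus_name is None:
                    idx.unmapped.append(rec)
                else:
                    idx.reads_by_locus.setdefault(rec.locus_name, []).append(rec)
        indexes.append(idx)
    return indexes


def build_dataset(
    individuals: Sequence[Individual],
    loci: Sequence[Locus],
    alignments: Sequence[AlignmentIndex],
) -> Dataset:
    """Cross-validate the three loaded inputs and assemble a :class:`Dataset`.

    Hard errors: an allele owned by an individual absent from the
    demographics; an alignment for an unknown individual. Warnings: an
    individual with no alignment file (it gets an empty index) and reads
    mapped to reference names that match no locus.
    """
    ind_map: Dict[str, Individual] = {}
    for ind in individuals:
        if ind.id in ind_map:
            raise IngestError(f"duplicate individual id {ind.id!r}")
        ind_map[ind.id] = ind

    locus_map: Dict[str, Locus] = {}
    for locus in loci:
        if locus.name in locus_map:
            raise IngestError(f"duplicate locus name {locus.name!r}")
        for a in locus.alleles:
            if a.individual_id not in ind_map:
                raise IngestError(
                    f"locus {locus.name!r}: allele owner {a.individual_id!r} "
                    "is not in the demographic file"
                )
        locus_map[locus.name] = locus

    aln_map: Dict[str, AlignmentIndex] = {}
    for aln in alignments:
        if aln.individual_id not in ind_map:
            raise IngestError(
                f"alignment for unknown individual {aln.individual_id!r}"
            )
        if aln.individual_id in aln_map:
            raise IngestError(
                f"multiple alignment files for individual {aln.individual_id!r}"
            )
        aln_map[aln.individual_id] = aln

    unknown_refs: Dict[str, int] = {}
    for aln in aln_map.values():
        for ref, reads in aln.reads_by_locus.items():
            if ref not in locus_map:
                unknown_refs[ref] = unknown_refs.get(ref, 0) + len(reads)
    if unknown_refs:
        logger.warning(
            "reads mapped to reference names matching no locus: %s",
            ", ".join(f"{k} ({v} reads)" for k, v in sorted(unknown_refs.items())),
        )

    for iid in ind_map:
        if iid not in aln_map:
            logger.warning(
                "individual %s has no alignment file; read tallies will be 0", iid
            )
            aln_map[iid] = AlignmentIndex(individual_id=iid)

    return Dataset(
        individuals=ind_map,
        loci=locus_map,
        alignments=aln_map,
        individual_order=[ind.id for ind in individuals],
    )


def load_dataset(
    demographics: PathLike,
    loci_paths: Iterable[PathLike],
    bam_paths: Iterable[PathLike],
    *,
    header_pattern: str = DEFAULT_HEADER_PATTERN,
    sample_map: Optional[Mapping[PathLike, str]] = None,
) -> Dataset:
    """Convenience wrapper running the three loaders and the assembler."""
    return build_dataset(
        load_demographics(demographics),
        load_loci(loci_paths, header_pattern=header_pattern),
        load_alignments(bam_paths, sample_map=sample_map),
    )
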