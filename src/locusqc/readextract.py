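"""Export the raw reads underlying a locus as multi-FASTA.

Each of the three coverage tallies in the locus table has a matching export
scope, so the number of records written always equals the coverage value
shown for the same (locus, scope) pair:

* ``this_ind`` — one individual's reads on the locus;
* ``total`` — every individual's reads on the locus;
* ``used`` — reads from only the individuals present in the final locus.

Reads that the aligner placed on the reverse strand are reverse-complemented
back to their original sequencer orientation by default, so the FASTA holds
the raw reads (set ``orient_original=False`` to keep alignment orientation).
Soft-clipped bases are retained because SAM stores them in SEQ; hard-clipped
bases were removed upstream and cannot be recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

from .model import Dataset, ReadRecord

logger = logging.getLogger(__name__)

__all__ = ["ReadExportRequest", "extract_reads", "unique_path"]

WRAP = 70


@dataclass(frozen=True)
class ReadExportRequest:
    """A request to export the reads under one locus.

    ``scope`` mirrors the coverage scopes; ``individual_id`` is required for
    ``this_ind``. ``out_dir`` receives a file named ``<locus>_<scope>.fasta``
    (suffixed ``_1``, ``_2``, ... if the name is taken).
    """

    locus_name: str
    scope: str  # this_ind | total | used
    out_dir: Union[str, Path]
    individual_id: Optional[str] = None


def unique_path(directory: Path, stem: str, suffix: str) -> Path:
    """First non-existing path ``directory/stem{,_1,_2,...}suffix``."""
    candidate = directory / f"{stem}{suffix}"
    counter = 1
    while candidate.exists():
        candidate = directory / f"{stem}_{counter}{suffix}"
        counter += 1
    return candidate


def _qualifying_reads(dataset: Dataset, request: ReadExportRequest) -> List[ReadRecord]:
    locus = dataset.loci.get(request.locus_name)
    if locus is None:
        raise KeyError(f"unknown locus {request.locus_name!r}")
    if request.scope == "this_ind":
        if request.individual_id is None:
            raise ValueError("scope 'this_ind' requires individual_id")
        if request.individual_id not in dataset.individuals:
            raise KeyError(f"unknown individual {request.individual_id!r}")
        members = [request.individual_id]
    elif request.scope == "total":
        members = list(dataset.individual_order)
    elif request.scope == "used":
        members = [i for i in dataset.individual_order if i in locus.individual_ids]
    else:
        raise ValueError(f"unknown scope {request.scope!r}")
    reads: List[ReadRecord] = []
    for iid in members:
        aln = dataset.alignments.get(iid)
        if aln:
            reads.extend(aln.reads_by_locus.get(request.locus_name, []))
    return reads


def extract_reads(
    dataset: Dataset,
    request: ReadExportRequest,
    *,
    orient_original: bool = True,
    header_delimiter: str = "|",
) -> Tuple[Optional[Path], int]:
    """Write the qualifying reads as multi-FASTA; return (path, count).

    Record headers are ``readID|individualID|locusName`` (delimiter
    configurable). With zero qualifying reads no file is created and
    ``(None, 0)`` is returned with a warning. The written path is logged.
    """
    reads = _qualifying_reads(dataset, request)
    if not reads:
        logger.warning(
            "no reads to export for locus %s (scope %s); no file written",
            request.locus_name,
            request.scope,
        )
        return None, 0
    out_dir = Path(request.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scope_tag = (
        f"{request.scope}_{request.individual_id}"
        if request.scope == "this_ind"
        else request.scope
    )
    path = unique_path(out_dir, f"{request.locus_name}_{scope_tag}", ".fasta")
    with path.open("w", encoding="utf-8") as fh:
        for read in reads:
            seq = (
                read.original_orientation_sequence()
                if orient_original
                else read.sequence
            )
            header = header_delimiter.join(
                [read.read_id, read.individual_id, request.locus_name]
            )
            fh.write(f">{header}\n")
            for i in range(0, len(seq), WRAP):
                fh.write(seq[i : i + WRAP] + "\n")
    logger.info("wrote %d reads to %s", len(reads), path)
    return path, len(reads)
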