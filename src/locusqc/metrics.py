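"""Per-individual and per-locus suitability statistics.

Two report tables summarise a :class:`~locusqc.model.Dataset`:

* the **summary table** — one row per individual: population, number of loci
  the individual was called in, total/used read counts and the used
  fraction;
* the **locus table** — one row per locus an individual was called in:
  alignment length, number of segregating sites, number of individuals
  called, and three read-coverage tallies (this individual / all
  individuals / individuals present in the final locus).

"Coverage" throughout is the count of primary mapped reads on the locus
reference, not per-base depth: enrichment loci are short, so read count is
the natural unit and is exactly what the read-extraction module exports.

Segregating sites are counted from the aligned allele sequences alone —
alignment files play no part. Two dialects exist: the default ignores gaps,
``N`` and IUPAC ambiguity codes when judging a column (a column ``{A, -, A}``
is invariant, ``{A, -, G}`` is variable); strict mode counts any character
difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional

from .model import Dataset, Locus

__all__ = [
    "SummaryRow",
    "LocusRow",
    "count_snps",
    "num_inds",
    "coverage",
    "summary_table",
    "locus_table",
]

_UNAMBIGUOUS = frozenset("ACGT")

SnpDialect = Literal["ignore-ambiguous", "strict"]
CoverageScope = Literal["this_ind", "total", "used"]


@dataclass(frozen=True)
class SummaryRow:
    """One summary-table row (per individual)."""

    individual_id: str
    population: str
    num_loci: int
    total_reads: int
    used_reads: int
    percent_used: float  # fraction in [0, 1]


@dataclass(frozen=True)
class LocusRow:
    """One locus-table row (per locus, for a focal individual)."""

    locus_name: str
    length: int
    snps: int
    number_inds: int
    coverage_this_ind: int
    coverage_total: int
    coverage_used: int


def count_snps(locus: Locus, *, dialect: SnpDialect = "ignore-ambiguous") -> int:
    """Count segregating (polymorphic) columns in the locus alignment.

    In the default dialect a column is variable when it holds at least two
    distinct characters from {A, C, G, T}; gaps, N and ambiguity codes are
    ignored. In ``strict`` mode any two distinct characters make a column
    variable. A single-allele locus has no observable variation and returns 0.
    """
    if not locus.alleles:
        raise ValueError(f"locus {locus.name!r} has no alleles")
    seqs = [a.sequence.upper() for a in locus.alleles]
    snps = 0
    for column in zip(*seqs):
        if dialect == "strict":
            chars = set(column)
        else:
            chars = set(column) & _UNAMBIGUOUS
        if len(chars) >= 2:
            snps += 1
    return snps


def num_inds(locus: Locus) -> int:
    """Number of distinct individuals called at this locus (a diploid's two
    alleles count once)."""
    return len(locus.individual_ids)


def coverage(
    dataset: Dataset,
    locus_name: str,
    scope: CoverageScope,
    individual_id: Optional[str] = None,
) -> int:
    """Read coverage for a locus under one of three scopes.

    ``this_ind``
        primary mapped reads of ``individual_id`` on the locus reference;
    ``total``
        summed over every individual in the dataset;
    ``used``
        summed over only the individuals present in the locus's final
        allele set.
    """
    if locus_name not in dataset.loci:
        raise KeyError(f"unknown locus {locus_name!r}")
    if scope == "this_ind":
        if individual_id is None:
            raise ValueError("scope 'this_ind' requires individual_id")
        if individual_id not in dataset.individuals:
            raise KeyError(f"unknown individual {individual_id!r}")
        aln = dataset.alignments.get(individual_id)
        return aln.count(locus_name) if aln else 0
    if scope == "total":
        members = dataset.individuals.keys()
    elif scope == "used":
        members = dataset.loci[locus_name].individual_ids
    else:
        raise ValueError(f"unknown scope {scope!r}")
    total = 0
    for iid in members:
        aln = dataset.alignments.get(iid)
        if aln:
            total += aln.count(locus_name)
    return total


def summary_table(dataset: Dataset) -> List[SummaryRow]:
    """One :class:`SummaryRow` per individual, in demographic-file order."""
    rows: List[SummaryRow] = []
    for iid in dataset.individual_order:
        ind = dataset.individuals[iid]
        aln = dataset.alignments[iid]
        n_loci = sum(1 for locus in dataset.loci.values() if iid in locus.individual_ids)
        total = aln.total_reads
        used = aln.used_reads
        rows.append(
            SummaryRow(
                individual_id=iid,
                population=ind.population,
                num_loci=n_loci,
                total_reads=total,
                used_reads=used,
                percent_used=(used / total) if total > 0 else 0.0,
            )
        )
    return rows


def locus_table(
    dataset: Dataset,
    individual_id: str,
    *,
    dialect: SnpDialect = "ignore-ambiguous",
) -> List[LocusRow]:
    """One :class:`LocusRow` per locus whose allele set contains
    ``individual_id``, in locus-name lexicographic order."""
    if individual_id not in dataset.individuals:
        raise KeyError(f"unknown individual {individual_id!r}")
    rows: List[LocusRow] = []
    for name in sorted(dataset.loci):
        locus = dataset.loci[name]
        if individual_id not in locus.individual_ids:
            continue
        rows.append(
            LocusRow(
                locus_name=name,
                length=locus.length,
                snps=count_snps(locus, dialect=dialect),
                number_inds=num_inds(locus),
                coverage_this_ind=coverage(dataset, name, "this_ind", individual_id),
                coverage_total=coverage(dataset, name, "total"),
                coverage_used=coverage(dataset, name, "used"),
            )
        )
    return rows
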