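"""Locus-subset selection and serialization to TSV, NEXUS, IMa2 and Migrate-n.

Selection semantics
-------------------
A :class:`SelectionSpec` names either individuals or populations:

* ``individuals`` mode keeps the loci whose allele set contains **every**
  listed individual (select all individuals and only complete loci remain);
* ``populations`` mode keeps the loci containing **at least one** individual
  from **each** listed population.

The phased allele — not the individual — is the sequence unit in every
output format: each allele is one terminal/sequence row.

Dialect notes
-------------
NEXUS is written one file per locus (loci have unequal taxon sets; a
concatenated supermatrix with ``?`` padding is available but non-default).
IMa2 defaults to the HKY mutation-model code ``H`` and inheritance scalar
1.0 (autosomal nuclear); the population tree is never invented — it must be
supplied whenever two or more populations are exported. IMa2 and Migrate-n
use fixed-width name fields (default 10 characters) with deterministic
suffixing when truncation collides.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .metrics import LocusRow, SummaryRow
from .model import Dataset, Locus
from .readextract import unique_path

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionSpec",
    "ExportConfig",
    "select_loci",
    "format_tsv",
    "write_tsv",
    "read_summary_tsv",
    "read_locus_tsv",
    "write_nexus",
    "read_nexus",
    "write_ima2",
    "read_ima2",
    "write_migrate",
    "read_migrate",
]

SUMMARY_COLUMNS = [
    "Individual",
    "Population",
    "numLoci",
    "totalReads",
    "usedReads",
    "percentUsed",
]
LOCUS_COLUMNS = [
    "LocusName",
    "Length",
    "SNPs",
    "Number_Inds",
    "Coverage_This_Ind",
    "Coverage_Total",
    "Coverage_Used",
]


class ExportError(ValueError):
    """Hard error while selecting or serializing loci."""


@dataclass(frozen=True)
class SelectionSpec:
    """Which loci to export: by individual ids or by population names."""

    mode: str  # "individuals" | "populations"
    members: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("individuals", "populations"):
            raise ExportError(f"unknown selection mode {self.mode!r}")
        if not self.members:
            raise ExportError("selection needs at least one member")
        object.__setattr__(self, "members", tuple(self.members))


@dataclass
class ExportConfig:
    """Format knobs for the IMa2/Migrate writers."""

    ima2_population_tree: Optional[str] = None
    ima2_mutation_model: str = "H"
    ima2_inheritance_scalar: float = 1.0
    name_width: int = 10


def select_loci(dataset: Dataset, spec: SelectionSpec) -> List[Locus]:
    """Resolve a :class:`SelectionSpec` to an ordered locus list.

    Returns the selected loci in locus-name lexicographic order. Unknown
    member names are a hard error.
    """
    if spec.mode == "individuals":
        for m in spec.members:
            if m not in dataset.individuals:
                raise ExportError(f"unknown individual {m!r} in selection")
        required = set(spec.members)
        keep = [
            locus
            for name, locus in sorted(dataset.loci.items())
            if required <= locus.individual_ids
        ]
    else:
        known_pops = set(dataset.populations())
        for m in spec.members:
            if m not in known_pops:
                raise ExportError(f"unknown population {m!r} in selection")
        pop_of = {iid: ind.population for iid, ind in dataset.individuals.items()}
        keep = []
        for name, locus in sorted(dataset.loci.items()):
            present = {pop_of[iid] for iid in locus.individual_ids}
            if set(spec.members) <= present:
                keep.append(locus)
    return keep


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def format_tsv(rows: Sequence[Union[SummaryRow, LocusRow]]) -> str:
    """Render summary or locus rows as TSV text with the report's canonical
    column headers; percentUsed is rendered as a percentage with one
    decimal. An empty row list yields a header-only summary table."""
    if rows and isinstance(rows[0], LocusRow):
        header = LOCUS_COLUMNS
        lines = [
            "\t".join(
                str(v)
                for v in (
                    r.locus_name,
                    r.length,
                    r.snps,
                    r.number_inds,
                    r.coverage_this_ind,
                    r.coverage_total,
                    r.coverage_used,
                )
            )
            for r in rows
        ]
    else:
        header = SUMMARY_COLUMNS
        lines = [
            "\t".join(
                (
                    r.individual_id,
                    r.population,
                    str(r.num_loci),
                    str(r.total_reads),
                    str(r.used_reads),
                    f"{100 * r.percent_used:.1f}",
                )
            )
            for r in rows
        ]
    return "\t".join(header) + "\n" + "".join(l + "\n" for l in lines)


def write_tsv(
    rows: Sequence[Union[SummaryRow, LocusRow]],
    path: Union[str, Path],
) -> Path:
    """Serialize rows via :func:`format_tsv` to a UTF-8 file."""
    path = Path(path)
    path.write_text(format_tsv(rows), encoding="utf-8")
    logger.info("wrote %d rows to %s", len(rows), path)
    return path


def read_summary_tsv(path: Union[str, Path]) -> List[SummaryRow]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != SUMMARY_COLUMNS:
        raise ExportError(f"{path}: not a summary TSV")
    rows = []
    for line in lines[1:]:
        iid, pop, n_loci, total, used, pct = line.split("\t")
        rows.append(
            SummaryRow(
                individual_id=iid,
                population=pop,
                num_loci=int(n_loci),
                total_reads=int(total),
                used_reads=int(used),
                percent_used=float(pct) / 100.0,
            )
        )
    return rows


def read_locus_tsv(path: Union[str, Path]) -> List[LocusRow]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != LOCUS_COLUMNS:
        raise ExportError(f"{path}: not a locus TSV")
    rows = []
    for line in lines[1:]:
        name, length, snps, ninds, cov_i, cov_t, cov_u = line.split("\t")
        rows.append(
            LocusRow(
                locus_name=name,
                length=int(length),
                snps=int(snps),
                number_inds=int(ninds),
                coverage_this_ind=int(cov_i),
                coverage_total=int(cov_t),
                coverage_used=int(cov_u),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

_NEXUS_SAFE = re.compile(r"^[A-Za-z0-9_.]+$")


def _nexus_label(label: str) -> str:
    """Quote a taxon label unless it is already a NEXUS-safe token."""
    if _NEXUS_SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _allele_label(individual_id: str, allele_index: int) -> str:
    return f"{individual_id}_{allele_index}"


def write_nexus(
    loci: Sequence[Locus],
    dataset: Dataset,
    out_dir: Union[str, Path],
    *,
    concat: bool = False,
) -> List[Path]:
    """Write one NEXUS file per locus (or one concatenated supermatrix).

    Each file holds a DATA block with the locus's phased alleles; taxon
    labels are ``individual_allele``. In concatenated mode, alleles missing
    from a locus are padded with ``?``.
    """
    if not loci:
        raise ExportError("no loci to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    if concat:
        labels: List[str] = []
        for locus in loci:
            for a in locus.alleles:
                lab = _allele_label(a.individual_id, a.allele_index)
                if lab not in labels:
                    labels.append(lab)
        matrix = {lab: [] for lab in labels}
        for locus in loci:
            present = {
                _allele_label(a.individual_id, a.allele_index): a.sequence
                for a in locus.alleles
            }
            for lab in labels:
                matrix[lab].append(present.get(lab, "?" * locus.length))
        nchar = sum(l.length for l in loci)
        path = unique_path(out_dir, "concatenated", ".nex")
        _write_nexus_matrix(
            path, [(lab, "".join(parts)) for lab, parts in matrix.items()], nchar
        )
        paths.append(path)
    else:
        for locus in loci:
            path = unique_path(out_dir, locus.name, ".nex")
            rows = [
                (_allele_label(a.individual_id, a.allele_index), a.sequence)
                for a in locus.alleles
            ]
            _write_nexus_matrix(path, rows, locus.length)
            paths.append(path)
    for p in paths:
        logger.info("wrote NEXUS %s", p)
    return paths


def _write_nexus_matrix(path: Path, rows: List[Tuple[str, str]], nchar: int) -> None:
    width = max(len(_nexus_label(lab)) for lab, _ in rows) + 2
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#NEXUS\n")
        fh.write("BEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(rows)} NCHAR={nchar};\n")
        fh.write("    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n")
        fh.write("    MATRIX\n")
        for lab, seq in rows:
            fh.write(f"    {_nexus_label(lab):<{width}}{seq}\n")
        fh.write("    ;\n")
        fh.write("END;\n")


def read_nexus(path: Union[str, Path]) -> Dict[str, str]:
    """Strictly parse one of our NEXUS files back to {taxon: sequence}."""
    text = Path(path).read_text(encoding="utf-8")
    if not text.startswith("#NEXUS"):
        raise ExportError(f"{path}: missing #NEXUS header")
    m = re.search(r"DIMENSIONS\s+NTAX=(\d+)\s+NCHAR=(\d+);", text)
    if not m:
        raise ExportError(f"{path}: missing DIMENSIONS")
    ntax, nchar = int(m.group(1)), int(m.group(2))
    matrix_match = re.search(r"MATRIX\n(.*?)\n\s*;", text, re.S)
    if not matrix_match:
        raise ExportError(f"{path}: missing MATRIX block")
    result: Dict[str, str] = {}
    for line in matrix_match.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            end = line.index("'", 1)
            while end + 1 < len(line) and line[end + 1] == "'":
                end = line.index("'", end + 2)
            label = line[1:end].replace("''", "'")
            seq = line[end + 1 :].strip()
        else:
            label, seq = line.split(None, 1)
        if len(seq) != nchar:
            raise ExportError(f"{path}: {label} has {len(seq)} chars, NCHAR={nchar}")
        if label in result:
            raise ExportError(f"{path}: duplicate taxon {label!r}")
        result[label] = seq
    if len(result) != ntax:
        raise ExportError(f"{path}: {len(result)} taxa found, NTAX={ntax}")
    return result


# ---------------------------------------------------------------------------
# fixed-width labels for IMa2 / Migrate
# ---------------------------------------------------------------------------

def _fixed_width_labels(labels: Sequence[str], width: int) -> List[str]:
    """Pad/truncate labels to ``width`` characters; resolve truncation
    collisions with deterministic numeric suffixes."""
    out: List[str] = []
    seen: Dict[str, int] = {}
    for lab in labels:
        short = lab[:width]
        if short in seen:
            seen[short] += 1
            suffix = str(seen[short])
            short = short[: width - len(suffix)] + suffix
        else:
            seen[short] = 0
        out.append(short.ljust(width))
    return out


def _alleles_by_population(
    locus: Locus, dataset: Dataset, populations: Sequence[str]
) -> Dict[str, List]:
    by_pop: Dict[str, List] = {p: [] for p in populations}
    for a in locus.alleles:
        pop = dataset.individuals[a.individual_id].population
        if pop in by_pop:
            by_pop[pop].append(a)
    return by_pop


# ---------------------------------------------------------------------------
# IMa2
# ---------------------------------------------------------------------------

def write_ima2(
    loci: Sequence[Locus],
    dataset: Dataset,
    spec: SelectionSpec,
    config: ExportConfig,
    path: Union[str, Path],
) -> Path:
    """Write an IMa2 input file for the selected loci.

    Layout: comment line; number of populations; population names;
    population-tree string (``0`` for a single population); number of loci;
    then per locus a header ``name n1 ... nK length model scalar`` followed
    by one fixed-width-labelled sequence line per allele, grouped by
    population in population-name order.
    """
    if not loci:
        raise ExportError("no loci to write")
    populations = _selected_populations(dataset, spec)
    if len(populations) >= 2 and not config.ima2_population_tree:
        raise ExportError(
            "IMa2 export with 2+ populations requires ima2_population_tree "
            "(the tool will not invent a topology)"
        )
    tree = config.ima2_population_tree if len(populations) >= 2 else "0"
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# multi-locus export\n")
        fh.write(f"{len(populations)}\n")
        fh.write(" ".join(populations) + "\n")
        fh.write(f"{tree}\n")
        fh.write(f"{len(loci)}\n")
        for locus in loci:
            by_pop = _alleles_by_population(locus, dataset, populations)
            counts = [len(by_pop[p]) for p in populations]
            assert all(c > 0 for c in counts) or spec.mode == "individuals", (
                f"locus {locus.name}: selected population with zero alleles"
            )
            fh.write(
                f"{locus.name} "
                + " ".join(str(c) for c in counts)
                + f" {locus.length} {config.ima2_mutation_model} "
                + _format_scalar(config.ima2_inheritance_scalar)
                + "\n"
            )
            ordered = [a for p in populations for a in by_pop[p]]
            labels = _fixed_width_labels(
                [_allele_label(a.individual_id, a.allele_index) for a in ordered],
                config.name_width,
            )
            for lab, a in zip(labels, ordered):
                fh.write(f"{lab}{a.sequence}\n")
    logger.info("wrote IMa2 file %s", path)
    return path


def _format_scalar(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def _selected_populations(dataset: Dataset, spec: SelectionSpec) -> List[str]:
    """Populations covered by the selection, in dataset population order."""
    if spec.mode == "populations":
        order = dataset.populations()
        return [p for p in order if p in set(spec.members)]
    pops = {dataset.individuals[m].population for m in spec.members}
    return [p for p in dataset.populations() if p in pops]


def read_ima2(path: Union[str, Path]) -> Dict:
    """Strictly parse one of our IMa2 files; returns populations, tree and
    per-locus {name, counts, length, model, scalar, sequences-by-population}."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ExportError(f"{path}: IMa2 file must start with a comment line")
    npop = int(lines[1])
    populations = lines[2].split()
    if len(populations) != npop:
        raise ExportError(f"{path}: {len(populations)} population names, expected {npop}")
    tree = lines[3]
    nloci = int(lines[4])
    loci = []
    i = 5
    for _ in range(nloci):
        parts = lines[i].split()
        name = parts[0]
        counts = [int(c) for c in parts[1 : 1 + npop]]
        length = int(parts[1 + npop])
        model = parts[2 + npop]
        scalar = float(parts[3 + npop])
        i += 1
        seqs: Dict[str, List[Tuple[str, str]]] = {p: [] for p in populations}
        for p, n in zip(populations, counts):
            for _ in range(n):
                line = lines[i]
                label, seq = line[:10].strip(), line[10:].strip()
                # name_width other than 10 is recoverable from the length
                if len(seq) != length:
                    width = len(line) - length
                    label, seq = line[:width].strip(), line[width:]
                if len(seq) != length:
                    raise ExportError(
                        f"{path}: sequence length {len(seq)} != locus length {length}"
                    )
                seqs[p].append((label, seq))
                i += 1
        loci.append(
            {
                "name": name,
                "counts": counts,
                "length": length,
                "model": model,
                "scalar": scalar,
                "sequences": seqs,
            }
        )
    return {"populations": populations, "tree": tree, "loci": loci}


# ---------------------------------------------------------------------------
# Migrate-n
# ---------------------------------------------------------------------------

def write_migrate(
    loci: Sequence[Locus],
    dataset: Dataset,
    spec: SelectionSpec,
    path: Union[str, Path],
    *,
    name_width: int = 10,
) -> Path:
    """Write a Migrate-n sequence-format file for the selected loci.

    Layout: ``<numpop> <numloci>``; a line of locus lengths; then per
    population a header ``<n per locus ...> <population name>`` followed by
    that population's sequences for each locus in turn.
    """
    if not loci:
        raise ExportError("no loci to write")
    populations = _selected_populations(dataset, spec)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(populations)} {len(loci)}\n")
        fh.write(" ".join(str(l.length) for l in loci) + "\n")
        for pop in populations:
            per_locus = [
                _alleles_by_population(locus, dataset, [pop])[pop] for locus in loci
            ]
            fh.write(" ".join(str(len(a)) for a in per_locus) + f" {pop}\n")
            for alleles in per_locus:
                labels = _fixed_width_labels(
                    [_allele_label(a.individual_id, a.allele_index) for a in alleles],
                    name_width,
                )
                for lab, a in zip(labels, alleles):
                    fh.write(f"{lab}{a.sequence}\n")
    logger.info("wrote Migrate file %s", path)
    return path


def read_migrate(path: Union[str, Path], *, name_width: int = 10) -> Dict:
    """Strictly parse one of our Migrate-n files back to
    {populations: [...], lengths: [...], sequences: {pop: [[(label, seq), ...] per locus]}}."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    npop, nloci = (int(x) for x in lines[0].split())
    lengths = [int(x) for x in lines[1].split()]
    if len(lengths) != nloci:
        raise ExportError(f"{path}: {len(lengths)} locus lengths, expected {nloci}")
    i = 2
    populations: List[str] = []
    sequences: Dict[str, List[List[Tuple[str, str]]]] = {}
    for _ in range(npop):
        parts = lines[i].split()
        counts = [int(c) for c in parts[:nloci]]
        pop = " ".join(parts[nloci:])
        if not pop:
            raise ExportError(f"{path}: population header missing name: {lines[i]!r}")
        populations.append(pop)
        i += 1
        per_locus: List[List[Tuple[str, str]]] = []
        for locus_idx, n in enumerate(counts):
            block: List[Tuple[str, str]] = []
            for _ in range(n):
                line = lines[i]
                label, seq = line[:name_width].strip(), line[name_width:]
                if len(seq) != lengths[locus_idx]:
                    raise ExportError(
                        f"{path}: sequence length {len(seq)} != locus length "
                        f"{lengths[locus_idx]}"
                    )
                block.append((label, seq))
                i += 1
            per_locus.append(block)
        sequences[pop] = per_locus
    return {"populations": populations, "lengths": lengths, "sequences": sequences}
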