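"""Synthetic input generator with a ground-truth manifest.

Emulates the data shape of a small genome-enrichment study: a handful of
diploid individuals from a few populations, typed at short loci. For each
locus an ancestral sequence is drawn, a chosen number of segregating sites
is planted, and every individual called at the locus receives two phased
alleles over those variants. Reads are error-free full-length copies of the
alleles (coverage and SNP accounting are the test target, not caller
robustness; an ``error_rate`` knob exists but defaults to 0), written as
primary mapped records against the locus reference, plus a configurable
fraction of unmapped records. Individuals *not* called at a locus still
receive reads there (copies of the ancestral sequence), so "coverage used"
genuinely differs from "coverage total".

Everything the package consumes is emitted: per-locus aligned FASTAs with
the default ``>IND_ALLELE`` header convention, one sorted+indexed BAM (or
plain SAM) per individual, a demographic TSV, and a JSON
:class:`TruthManifest` recording every planted quantity so each metric and
selection result can be checked exactly. A fixed seed fixes the full output
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .model import reverse_complement

__all__ = ["SimParams", "TruthManifest", "GeneratedData", "generate", "example_fixture"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic study; defaults mirror a small 454-style
    enrichment dataset (a few diploid individuals, short loci, a fair
    fraction of reads left unmapped)."""

    n_individuals: int = 4
    n_populations: int = 2
    n_loci: int = 5
    locus_length_range: Tuple[int, int] = (100, 300)
    reads_per_individual_per_locus_range: Tuple[int, int] = (2, 20)
    unmapped_read_fraction: float = 0.3
    segregating_sites_per_locus_range: Tuple[int, int] = (0, 8)
    missing_individual_probability: float = 0.2
    reverse_strand_fraction: float = 0.3
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_individuals, self.n_populations, self.n_loci) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_populations > self.n_individuals and self.n_individuals > 0:
            raise ValueError("more populations than individuals")
        for frac in (
            self.unmapped_read_fraction,
            self.missing_individual_probability,
            self.reverse_strand_fraction,
            self.error_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.unmapped_read_fraction >= 1.0:
            raise ValueError("unmapped_read_fraction must be < 1")
        if self.segregating_sites_per_locus_range[1] > self.locus_length_range[0]:
            raise ValueError(
                "cannot plant more segregating sites than the shortest locus "
                f"({self.segregating_sites_per_locus_range[1]} > "
                f"{self.locus_length_range[0]})"
            )


@dataclass
class TruthManifest:
    """Ground truth for one generated dataset.

    ``individuals`` maps id → {population, total_reads, used_reads,
    num_loci}; ``loci`` maps name → {length, planted_snps,
    member_individuals, read_counts (per individual)}; ``selections`` lists
    enumerated selection requests with their expected locus subsets.
    """

    individuals: Dict[str, Dict] = field(default_factory=dict)
    loci: Dict[str, Dict] = field(default_factory=dict)
    selections: List[Dict] = field(default_factory=list)

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "individuals": self.individuals,
                    "loci": self.loci,
                    "selections": self.selections,
                },
                indent=1,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
        return path

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TruthManifest":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            individuals=data["individuals"],
            loci=data["loci"],
            selections=data["selections"],
        )


@dataclass
class GeneratedData:
    """Paths of one generated file tree plus its manifest."""

    root: Path
    demographics: Path
    loci_paths: List[Path]
    alignment_paths: List[Path]
    manifest_path: Path
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# internal in-memory design of a dataset before serialization
# ---------------------------------------------------------------------------

@dataclass
class _Design:
    # id -> (population, extra columns)
    individuals: Dict[str, Tuple[str, Dict[str, str]]]
    # locus name -> dict(length, snps, alleles={ind: (seq0, seq1)}, ancestral)
    loci: Dict[str, Dict]
    # ind -> list of (read_id, locus_or_None, seq_in_ref_orientation, is_reverse)
    reads: Dict[str, List[Tuple[str, Optional[str], str, bool]]]


def _design_to_manifest(design: _Design) -> TruthManifest:
    manifest = TruthManifest()
    mapped_counts: Dict[str, Dict[str, int]] = {i: {} for i in design.individuals}
    unmapped_counts: Dict[str, int] = {i: 0 for i in design.individuals}
    for iid, reads in design.reads.items():
        for _, locus, _, _ in reads:
            if locus is None:
                unmapped_counts[iid] += 1
            else:
                mapped_counts[iid][locus] = mapped_counts[iid].get(locus, 0) + 1
    for name in sorted(design.loci):
        spec = design.loci[name]
        members = sorted(spec["alleles"])
        manifest.loci[name] = {
            "length": spec["length"],
            "planted_snps": spec["snps"],
            "member_individuals": members,
            "read_counts": {
                iid: mapped_counts[iid].get(name, 0)
                for iid in design.individuals
                if mapped_counts[iid].get(name, 0) > 0
            },
        }
    for iid, (pop, _extra) in design.individuals.items():
        used = sum(mapped_counts[iid].values())
        manifest.individuals[iid] = {
            "population": pop,
            "total_reads": used + unmapped_counts[iid],
            "used_reads": used,
            "num_loci": sum(
                1 for spec in design.loci.values() if iid in spec["alleles"]
            ),
        }
    manifest.selections = _enumerate_selections(design)
    return manifest


def _enumerate_selections(design: _Design) -> List[Dict]:
    """Expected locus subsets for a few canonical selections, computed by
    direct set comprehension over the planted memberships."""
    members_of = {
        name: set(spec["alleles"]) for name, spec in design.loci.items()
    }
    pops: Dict[str, List[str]] = {}
    for iid, (pop, _) in design.individuals.items():
        pops.setdefault(pop, []).append(iid)
    selections: List[Dict] = []

    def add(mode: str, sel_members: Sequence[str], loci: List[str]) -> None:
        selections.append(
            {"mode": mode, "members": sorted(sel_members), "loci": sorted(loci)}
        )

    all_inds = sorted(design.individuals)
    add(
        "individuals",
        all_inds,
        [n for n, mem in members_of.items() if set(all_inds) <= mem],
    )
    for iid in all_inds:
        add("individuals", [iid], [n for n, mem in members_of.items() if iid in mem])
    all_pops = sorted(pops)
    add(
        "populations",
        all_pops,
        [
            n
            for n, mem in members_of.items()
            if all(any(i in mem for i in pops[p]) for p in all_pops)
        ],
    )
    for p in all_pops:
        add(
            "populations",
            [p],
            [n for n, mem in members_of.items() if any(i in mem for i in pops[p])],
        )
    return selections


# ---------------------------------------------------------------------------
# serialization of a design to the on-disk input formats
# ---------------------------------------------------------------------------

def _write_demographics(design: _Design, path: Path) -> None:
    extra_cols: List[str] = []
    for _, (_, extra) in design.individuals.items():
        for col in extra:
            if col not in extra_cols:
                extra_cols.append(col)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(["individual", "population", *extra_cols]) + "\n")
        for iid, (pop, extra) in design.individuals.items():
            fh.write(
                "\t".join([iid, pop, *(extra.get(c, "") for c in extra_cols)]) + "\n"
            )


def _write_loci(design: _Design, loci_dir: Path) -> List[Path]:
    loci_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(design.loci):
        spec = design.loci[name]
        path = loci_dir / f"{name}.fasta"
        with path.open("w", encoding="utf-8") as fh:
            for iid in sorted(spec["alleles"]):
                for idx, seq in enumerate(spec["alleles"][iid]):
                    fh.write(f">{iid}_{idx}\n{seq}\n")
        paths.append(path)
    return paths


def _write_alignment(
    design: _Design, iid: str, out_dir: Path, fmt: str
) -> Path:
    locus_names = sorted(design.loci)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": design.loci[name]["length"]} for name in locus_names
        ],
    }
    tid = {name: i for i, name in enumerate(locus_names)}
    mapped = [r for r in design.reads[iid] if r[1] is not None]
    unmapped = [r for r in design.reads[iid] if r[1] is None]
    mapped.sort(key=lambda r: (tid[r[1]], r[0]))

    def records(af: pysam.AlignmentFile):
        for read_id, locus, seq, is_reverse in mapped + unmapped:
            a = pysam.AlignedSegment(af.header)
            a.query_name = read_id
            a.query_sequence = seq
            if locus is None:
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            else:
                a.flag = 16 if is_reverse else 0
                a.reference_id = tid[locus]
                a.reference_start = 0
                a.mapping_quality = 60
                a.cigarstring = f"{len(seq)}M"
            yield a

    if fmt == "sam":
        path = out_dir / f"{iid}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as af:
            for a in records(af):
                af.write(a)
        return path
    path = out_dir / f"{iid}.bam"
    with pysam.AlignmentFile(str(path), "wb", header=header) as af:
        for a in records(af):
            af.write(a)
    pysam.index(str(path))
    return path


def _materialize(
    design: _Design, out_dir: Union[str, Path], *, alignment_format: str = "bam"
) -> GeneratedData:
    if alignment_format not in ("bam", "sam"):
        raise ValueError(f"unknown alignment format {alignment_format!r}")
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    demographics = root / "demographics.tsv"
    _write_demographics(design, demographics)
    loci_paths = _write_loci(design, root / "loci")
    aln_dir = root / "alignments"
    aln_dir.mkdir(exist_ok=True)
    alignment_paths = [
        _write_alignment(design, iid, aln_dir, alignment_format)
        for iid in design.individuals
    ]
    manifest = _design_to_manifest(design)
    manifest_path = manifest.save(root / "manifest.json")
    return GeneratedData(
        root=root,
        demographics=demographics,
        loci_paths=loci_paths,
        alignment_paths=alignment_paths,
        manifest_path=manifest_path,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def generate(
    params: SimParams,
    out_dir: Union[str, Path],
    *,
    alignment_format: str = "bam",
) -> GeneratedData:
    """Generate a complete synthetic input tree under ``out_dir``.

    Writes ``demographics.tsv``, ``loci/<name>.fasta``,
    ``alignments/<individual>.bam`` (+ ``.bai``; or ``.sam``) and
    ``manifest.json``; returns the paths and the parsed manifest. The same
    ``params`` (including seed) reproduce the outputs bit-for-bit.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    individuals: Dict[str, Tuple[str, Dict[str, str]]] = {}
    for i in range(params.n_individuals):
        pop_idx = i % params.n_populations if params.n_populations else 0
        individuals[f"I{i + 1:02d}"] = (
            f"pop{pop_idx + 1}",
            {"locality": f"site{pop_idx + 1}"},
        )
    ind_ids = list(individuals)

    lo_len, hi_len = params.locus_length_range
    lo_snp, hi_snp = params.segregating_sites_per_locus_range
    lo_rd, hi_rd = params.reads_per_individual_per_locus_range

    loci: Dict[str, Dict] = {}
    for j in range(params.n_loci):
        name = f"LOCUS_{101 + j}"
        length = int(rng.integers(lo_len, hi_len + 1))
        ancestral = _random_seq(rng, length)
        members = [
            iid
            for iid in ind_ids
            if rng.random() >= params.missing_individual_probability
        ]
        if not members:
            members = [ind_ids[int(rng.integers(0, len(ind_ids)))]]
        n_snps = int(rng.integers(lo_snp, hi_snp + 1))
        if n_snps > length:
            raise ValueError(f"{name}: {n_snps} segregating sites > length {length}")
        sites = sorted(int(s) for s in rng.choice(length, size=n_snps, replace=False))
        # haplotype rows: two per member, varying only at the planted sites
        rows = [list(ancestral) for _ in range(2 * len(members))]
        for site in sites:
            ref = ancestral[site]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            picks = rng.integers(0, 2, size=len(rows))
            # force both states to occur so the column is truly segregating
            picks[0], picks[1] = 0, 1
            for row, pick in zip(rows, picks):
                row[site] = alt if pick else ref
        alleles = {
            iid: ("".join(rows[2 * k]), "".join(rows[2 * k + 1]))
            for k, iid in enumerate(members)
        }
        loci[name] = {
            "length": length,
            "snps": n_snps,
            "ancestral": ancestral,
            "alleles": alleles,
        }

    reads: Dict[str, List[Tuple[str, Optional[str], str, bool]]] = {
        iid: [] for iid in ind_ids
    }
    for name in sorted(loci):
        spec = loci[name]
        for iid in ind_ids:
            n_reads = int(rng.integers(lo_rd, hi_rd + 1))
            templates = spec["alleles"].get(iid, (spec["ancestral"],) * 2)
            for r in range(n_reads):
                seq = templates[int(rng.integers(0, 2))]
                seq = _mutate(rng, seq, params.error_rate)
                is_reverse = bool(rng.random() < params.reverse_strand_fraction)
                reads[iid].append((f"{iid}.{name}.r{r + 1}", name, seq, is_reverse))
    f = params.unmapped_read_fraction
    mean_len = (lo_len + hi_len) // 2
    for iid in ind_ids:
        n_mapped = len(reads[iid])
        n_unmapped = int(round(n_mapped * f / (1.0 - f)))
        for r in range(n_unmapped):
            reads[iid].append(
                (f"{iid}.unmapped.r{r + 1}", None, _random_seq(rng, mean_len), False)
            )

    design = _Design(individuals=individuals, loci=loci, reads=reads)
    return _materialize(design, out_dir, alignment_format=alignment_format)


def example_fixture(
    out_dir: Union[str, Path], *, alignment_format: str = "bam"
) -> GeneratedData:
    """Deterministic canned dataset: four individuals (A–D, two populations)
    and two loci, LOCUS_101 containing all four individuals and LOCUS_102
    missing D (D still has reads there). Used in docs and smoke tests."""
    rng = np.random.default_rng(42424242)
    individuals = {
        "A": ("north", {"locality": "marsh1"}),
        "B": ("north", {"locality": "marsh1"}),
        "C": ("south", {"locality": "marsh2"}),
        "D": ("south", {"locality": "marsh2"}),
    }
    design_loci: Dict[str, Dict] = {}
    plans = [
        ("LOCUS_101", 40, ["A", "B", "C", "D"], [7, 23]),
        ("LOCUS_102", 30, ["A", "B", "C"], [11]),
    ]
    for name, length, members, sites in plans:
        ancestral = _random_seq(rng, length)
        rows = [list(ancestral) for _ in range(2 * len(members))]
        for site in sites:
            ref = ancestral[site]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            picks = rng.integers(0, 2, size=len(rows))
            picks[0], picks[1] = 0, 1
            for row, pick in zip(rows, picks):
                row[site] = alt if pick else ref
        design_loci[name] = {
            "length": length,
            "snps": len(sites),
            "ancestral": ancestral,
            "alleles": {
                iid: ("".join(rows[2 * k]), "".join(rows[2 * k + 1]))
                for k, iid in enumerate(members)
            },
        }
    read_plan = {
        "LOCUS_101": {"A": 12, "B": 8, "C": 6, "D": 4},
        "LOCUS_102": {"A": 5, "B": 5, "C": 5, "D": 3},
    }
    unmapped_plan = {"A": 2, "B": 1, "C": 0, "D": 1}
    reads: Dict[str, List[Tuple[str, Optional[str], str, bool]]] = {
        iid: [] for iid in individuals
    }
    for name in sorted(design_loci):
        spec = design_loci[name]
        for iid, n in read_plan[name].items():
            templates = spec["alleles"].get(iid, (spec["ancestral"],) * 2)
            for r in range(n):
                seq = templates[int(rng.integers(0, 2))]
                is_reverse = bool(rng.random() < 0.3)
                reads[iid].append((f"{iid}.{name}.r{r + 1}", name, seq, is_reverse))
    for iid, n in unmapped_plan.items():
        for r in range(n):
            reads[iid].append(
                (f"{iid}.unmapped.r{r + 1}", None, _random_seq(rng, 35), False)
            )
    design = _Design(individuals=individuals, loci=design_loci, reads=reads)
    return _materialize(design, out_dir, alignment_format=alignment_format)
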