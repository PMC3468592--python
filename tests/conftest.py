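"""Shared fixtures: generated file trees and in-memory dataset builders."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from locusqc import ingest, synthdata
from locusqc.model import (
    AlignmentIndex,
    AlleleSequence,
    Dataset,
    Individual,
    Locus,
    ReadRecord,
)


@pytest.fixture(scope="session")
def example(tmp_path_factory) -> synthdata.GeneratedData:
    """The canned four-individual, two-locus dataset on disk."""
    return synthdata.example_fixture(tmp_path_factory.mktemp("example"))


@pytest.fixture(scope="session")
def example_dataset(example) -> Dataset:
    return ingest.load_dataset(example.demographics, example.loci_paths, example.alignment_paths)


@pytest.fixture(scope="session")
def synth(tmp_path_factory) -> synthdata.GeneratedData:
    """A mid-sized random synthetic dataset (8 individuals, 3 populations,
    12 loci) used across modules."""
    params = synthdata.SimParams(
        n_individuals=8, n_populations=3, n_loci=12, seed=11
    )
    return synthdata.generate(params, tmp_path_factory.mktemp("synth"))


@pytest.fixture(scope="session")
def synth_dataset(synth) -> Dataset:
    return ingest.load_dataset(
        synth.demographics, synth.loci_paths, synth.alignment_paths
    )


def make_dataset(
    memberships: Dict[str, Sequence[str]],
    populations: Dict[str, str],
    read_counts: Dict[str, Dict[str, int]] | None = None,
    locus_length: int = 12,
) -> Dataset:
    """Build an in-memory Dataset from locus→members and individual→population
    maps; optional read_counts maps individual → {locus: n mapped reads}."""
    individuals = {
        iid: Individual(id=iid, population=pop) for iid, pop in populations.items()
    }
    loci = {}
    for name, members in memberships.items():
        alleles = tuple(
            AlleleSequence(individual_id=m, allele_index=k, sequence="A" * locus_length)
            for m in members
            for k in (0, 1)
        )
        loci[name] = Locus(name=name, alleles=alleles, length=locus_length)
    alignments = {}
    for iid in individuals:
        idx = AlignmentIndex(individual_id=iid)
        for locus, n in (read_counts or {}).get(iid, {}).items():
            idx.reads_by_locus[locus] = [
                ReadRecord(
                    read_id=f"{iid}.{locus}.{k}",
                    sequence="A" * locus_length,
                    individual_id=iid,
                    locus_name=locus,
                )
                for k in range(n)
            ]
        alignments[iid] = idx
    return Dataset(individuals=individuals, loci=loci, alignments=alignments)


def random_membership_dataset(
    rng: np.random.Generator,
    max_individuals: int = 10,
    max_populations: int = 4,
    max_loci: int = 20,
) -> Dataset:
    """Random in-memory dataset for selection-semantics property tests."""
    n_ind = int(rng.integers(1, max_individuals + 1))
    n_pop = int(rng.integers(1, min(n_ind, max_populations) + 1))
    n_loci = int(rng.integers(1, max_loci + 1))
    populations = {f"i{k}": f"p{int(rng.integers(0, n_pop))}" for k in range(n_ind)}
    memberships = {}
    ind_ids = list(populations)
    for j in range(n_loci):
        members = [iid for iid in ind_ids if rng.random() < 0.6]
        if not members:
            members = [ind_ids[int(rng.integers(0, n_ind))]]
        memberships[f"L{j:02d}"] = members
    return make_dataset(memberships, populations)
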