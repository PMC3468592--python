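# locusqc

Genome-enrichment methods (RAD-tags, amplicon sequencing, CRoPS, sequence
capture) plus next-generation sequencing yield uneven coverage across the
loci they target. Before a multi-locus dataset goes into phylogeographic or
population-genetic analysis, a researcher needs to know — per locus and per
individual — how many reads support each call, how polymorphic each locus
is, and which loci actually contain the individuals or populations a given
analysis requires. That bookkeeping lives in BAM alignments, per-locus
FASTA genotype files and a demographic table, and is tedious to extract by
hand.

`locusqc` is a headless library + CLI that collates those three inputs,
computes the suitability statistics, extracts the raw reads underlying any
locus, and reformats filtered locus subsets for downstream coalescent and
phylogenetic software.

## What it computes

From one sorted, indexed BAM (or SAM) per individual, one aligned
multi-FASTA of phased alleles per locus, and a tab-delimited demographic
file:

**Per individual** — population; `numLoci`, the number of loci the
individual was genotyped in; `totalReads`, every primary read in the BAM
(mapped + unmapped); `usedReads`, the primary reads mapped to any locus
reference; `percentUsed = usedReads / totalReads`.

**Per locus** — alignment length; `SNPs`, the number of segregating
columns in the allele alignment (a column is variable when it holds ≥ 2
distinct unambiguous bases; gaps, `N` and IUPAC ambiguity codes are
ignored by default, with a strict dialect that counts any difference);
`Number_Inds`, distinct individuals in the allele set; and three read
coverages, where coverage is the count of primary mapped reads on the
locus reference — for one individual (`Coverage_This_Ind`), summed over
all individuals (`Coverage_Total`), and summed over only the individuals
present in the final locus (`Coverage_Used`).

Locus subsets can be selected by **individuals** (keep loci containing
*every* listed individual) or by **populations** (keep loci containing at
least one member of *each* listed population) and written as per-locus
NEXUS files, a single IMa2 input file, or a Migrate-n sequence file, with
each phased allele as one terminal. The raw reads behind any coverage
number can be exported as multi-FASTA, reverse-strand reads
reverse-complemented back to sequencer orientation.

## Worked example

The package ships a deterministic example dataset — four diploid
individuals (A–D, two populations) at two loci, where LOCUS_102 lacks a
genotype for D even though D has reads there:

```sh
locusqc simulate --example --out-dir demo
locusqc summary -d demo/demographics.tsv -l demo/loci -a demo/alignments
```

```text
Individual	Population	numLoci	totalReads	usedReads	percentUsed
A	north	2	19	17	89.5
B	north	2	14	13	92.9
C	south	2	11	11	100.0
D	south	1	8	7	87.5
```

A sequenced 19 reads of which 17 mapped to a locus reference (89.5%), and
was genotyped at both loci; D was genotyped at only one. The per-locus view
for individual A:

```sh
locusqc locus-table A -d demo/demographics.tsv -l demo/loci -a demo/alignments
```

```text
LocusName	Length	SNPs	Number_Inds	Coverage_This_Ind	Coverage_Total	Coverage_Used
LOCUS_101	40	2	4	12	30	30
LOCUS_102	30	1	3	5	18	15
```

LOCUS_102 carries 18 reads in total but only 15 from the three individuals
actually genotyped there — D's 3 reads are aligned yet unused, which is
exactly the kind of locus one inspects for copy-number problems by
exporting its reads:

```sh
locusqc extract-reads LOCUS_102 --scope total -o exports \
    -d demo/demographics.tsv -l demo/loci -a demo/alignments
locusqc export --format migrate --mode populations -o exports \
    -d demo/demographics.tsv -l demo/loci -a demo/alignments
```

The first command writes 18 reads to `exports/LOCUS_102_total.fasta`; the
second selects the loci containing both populations (here: both loci) and
writes a Migrate-n input file. IMa2 export additionally needs
`--population-tree` whenever two or more populations are selected; NEXUS
export writes one file per locus. Every written file gets a unique name
and its path is logged.

`locusqc simulate` (without `--example`) generates random synthetic
datasets of configurable size, always alongside a `manifest.json` recording
every planted quantity — read counts per individual per locus, planted
segregating sites, locus membership — which is how the test suite verifies
the pipeline end to end.

## Layout

- `src/locusqc/ingest.py` — loaders and cross-file validation
- `src/locusqc/metrics.py` — SNP counting, coverage, report tables
- `src/locusqc/readextract.py` — raw-read FASTA export
- `src/locusqc/export.py` — locus selection; TSV/NEXUS/IMa2/Migrate writers and strict readers
- `src/locusqc/synthdata.py` — synthetic dataset generator + ground-truth manifest
- `src/locusqc/cli.py` — `locusqc` command-line interface
- `docs/methods.md` — models, conventions, numerical choices and limitations
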