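# Methods notes

## Data model and linkage contract

A dataset links three inputs. The demographic TSV defines the individuals
(first column id, second population — required on every row, with a
sentinel such as `NA` permitted when unknown; further columns are carried
through untouched). Each locus is an aligned multi-FASTA of phased alleles;
each individual has one SAM/BAM of reads aligned to a locus-level
reference. Because nothing in the inputs states the linkage explicitly, the
package imposes a naming contract: **a locus's FASTA file stem must equal
the BAM reference-sequence name**, and by default a BAM file's stem is the
individual id (overridable through the config `sample_map`). FASTA headers
follow `>INDIVIDUAL_ALLELEINDEX`, the *last* underscore splitting off the
allele index; genotype callers with other grammars are accommodated by a
configurable regex with named groups `individual`, `allele` and optionally
`locus`.

## Read counting

All tallies use primary alignment records only; secondary and
supplementary records are ignored, and a read pair counts as two reads
(one per primary record). `totalReads` is taken **from the BAM** as mapped
plus unmapped primaries. This is deliberate and loud: it requires users to
keep unmapped reads in their BAM (e.g. `bwa mem` default behaviour, or
`samtools view -b` without `-F 4`). A BAM stripped of unmapped records
will silently report `percentUsed = 100%`. We chose the BAM as the single
source rather than an auxiliary FASTQ count because it keeps one file
authoritative for every read-derived number.

"Coverage" is a read count per locus, not mean per-base depth: enrichment
loci are short (one read typically spans the locus), the count couples
1:1 with the read-export feature, and per-base depth would add no
discrimination at these scales.

## Segregating-site counting

SNPs are counted from the allele alignment alone — alignment files play no
part — by scanning columns. Two dialects:

* `ignore-ambiguous` (default): a column is variable iff it contains ≥ 2
  distinct characters from {A, C, G, T}. Gaps, `N` and IUPAC ambiguity
  codes are invisible to the test, so alignment padding cannot inflate the
  SNP count; `{A, -, A}` is invariant while `{A, -, G}` is variable.
* `strict`: any two distinct characters (case-insensitive) make a column
  variable.

The default is the lenient dialect because gap and ambiguity characters
encode uncertainty, not observed alleles. A single-allele locus returns 0:
no variation is observable from one sequence.

## Selection semantics

`individuals` mode keeps loci whose allele set contains **every** listed
individual; selecting all individuals therefore keeps only complete loci.
`populations` mode keeps loci containing **at least one** individual from
**each** listed population. Both are monotone: adding a member can only
shrink the result. When every selected population has exactly one member
the two modes coincide; both properties are enforced by oracle-based
property tests.

## Output formats

* **TSV** — the two report tables with canonical headers (`Individual`,
  `Population`, `numLoci`, `totalReads`, `usedReads`, `percentUsed` and
  `LocusName`, `Length`, `SNPs`, `Number_Inds`, `Coverage_This_Ind`,
  `Coverage_Total`, `Coverage_Used`). `percentUsed` is stored internally
  as a fraction and rendered as a percentage with one decimal.
* **NEXUS** — one file per locus by default, because loci have unequal
  taxon sets and a supermatrix would require missing-data padding; a
  concatenated option exists (`concat=True`) that pads absent alleles with
  `?`. Taxon labels are `individual_allele`, quoted per the standard when
  they are not bare tokens. Files are verified to re-parse both under the
  package's strict reader and under dendropy. Note the NEXUS convention
  that unquoted underscores read back as spaces in other software.
* **IMa2** — one file: comment line, population count, population names,
  population-tree line, locus count, then per locus a header
  `name n1 … nK length model scalar` and fixed-width-labelled sequences
  grouped by population. Defaults: mutation model `H` (HKY) and
  inheritance scalar 1.0 (autosomal nuclear), both overridable. The
  population tree is never invented: exporting ≥ 2 populations without one
  is a hard error; a single population writes the degenerate tree `0`.
* **Migrate-n** — `<numpop> <numloci>`, locus lengths, then per population
  a `<counts…> <name>` header followed by that population's sequences per
  locus.

IMa2/Migrate name fields are 10 characters by default; labels longer than
the field are truncated and disambiguated with deterministic numeric
suffixes. In all three formats each phased allele is one sequence row.
The original tool's exact NEXUS layout and IMa2 defaults are not
documented anywhere we could recover; ours are explicit dialect choices,
not claimed reproductions.

## Read extraction

Export scopes mirror the three coverage scopes, so the record count always
equals the displayed coverage number. Headers are
`readID|individualID|locusName` (delimiter configurable). Reverse-strand
reads are reverse-complemented so the FASTA holds sequencer-orientation
reads (`orient_original=False` keeps alignment orientation). Soft-clipped
bases are retained (SAM SEQ stores them); hard-clipped bases are
unrecoverable. Zero qualifying reads produce a warning and no file;
repeated exports never overwrite — filenames get `_1`, `_2`, … suffixes.

## Synthetic data generator

The generator emulates a small enrichment study: by default 4 diploid
individuals in 2 populations at 5 loci of 100–300 bp, 2–20 reads per
individual per locus, 30% of reads unmapped, 0–8 planted segregating
sites per locus, a 20% chance an individual is missing from a locus, and
30% of mapped reads on the reverse strand. These defaults are the shape of
a small 454-era RAD study — few individuals, short loci, a substantial
unmapped fraction — and are the conditions under which the test suite
runs.

Per locus it draws an ancestral sequence, plants the drawn number of
segregating sites (forcing both states to occur so every planted site is
truly polymorphic and the planted count equals the column-scan count
exactly), and gives each member individual two alleles over those
variants. Reads are error-free full-length allele copies (an `error_rate`
knob exists, default 0); individuals *not* genotyped at a locus still
receive reads there (ancestral copies), so `Coverage_Used` genuinely
differs from `Coverage_Total`. Unmapped reads are added per individual so
the unmapped fraction matches the parameter. BAMs are written
coordinate-sorted with an index, exercising the real ingest requirement;
plain SAM output is available. A fixed seed fixes every output byte.

What the generator does **not** emulate: sequencing error and quality
strings, indel alignment (reads are gapless full-length matches), paired
ends, coverage-dependent genotype-calling thresholds, and paralogous
multi-copy loci. Passing tests therefore demonstrate correct accounting
and formatting on clean data, not robustness of upstream callers.

## Numerical and degenerate-input choices

`percentUsed` is defined as 0 when an individual has no reads. An empty
locus list yields a valid dataset whose summary shows `numLoci = 0`. An
individual present in demographics but lacking a BAM gets an empty
alignment index plus a warning; reads mapped to reference names matching
no locus are tallied and warned about after assembly, and are still
counted in `usedReads`. Ties and orderings are made deterministic
everywhere: summary rows follow demographic-file order, locus tables and
selections are locus-name lexicographic.

## Problem sizes

The test suite and the acceptance script run entirely on generated data at
desk scale: the end-to-end batch uses 20 randomized datasets of up to 10
individuals, 3 populations and 50 loci; oracle sweeps use 1000 random
alignments (SNP counting) and 500 random datasets (selection). These sizes
give complete coverage of the combinatorics while keeping a full run in
the seconds-to-a-minute range on one CPU.

## Known limitations

* `totalReads` is only as meaningful as the BAM's unmapped-read retention
  (see above).
* Hard-clipped bases cannot be restored on read export.
* The IMa2 population tree is passed through verbatim; its topology is not
  validated against the population count.
* BAM ingest holds read records in memory; the design targets
  enrichment-scale datasets (thousands–millions of reads), not whole
  genomes.
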