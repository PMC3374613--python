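# Methods

This note documents the models and procedures implemented in `mockmap`,
the defaults chosen where the design was open, and what the synthetic
benchmark does and does not demonstrate.

## Reference database model

A database is a set of strain genomes. Every FASTA record ID carries a
short strain prefix (`<prefix>_<original id>`), so any alignment resolves
to a strain, and each strain carries a lineage (species, genus,
superkingdom) through a tab-separated index. Sequences whose ID or
description contains "plasmid" are tracked separately from the chromosome:
they are excluded from the redundancy screen but count toward strain length
and coverage, because the final database carries the plasmids of every kept
strain. Coordinates are 0-based half-open everywhere internally; SAM output
converts to 1-based.

### Genome similarity and dereplication

Pairwise genome similarity is measured by canonical k-mer containment
(default k = 21): the number of distinct strand-minimal k-mers shared by
the two genomes, divided by the distinct-k-mer count of the k-mer-poorer
genome. Containment rather than Jaccard is used deliberately: a genome that
is essentially a subset of another scores near 1 and is the right candidate
for removal, matching the goal of eliminating genomes that contribute
little unique sequence.

Containment is not on the percent-identity scale in which dereplication
thresholds are conventionally quoted (2% divergence gives only ~0.65
containment at k = 21), so the dereplication step converts containment C to
an identity estimate `ANI ≈ 1 + ln(C)/k` — the Mash-distance estimator,
exact under independent substitutions — and applies the threshold (default
0.90; 0.83 in relaxed mode) to that estimate. `genome_similarity` itself
returns raw containment; the conversion lives in `dereplicate` and the
identity estimate is what the removal log records.

Within each species, genomes are visited longest-chromosome-first
(lexicographic prefix as tie-break, making the procedure deterministic) and
greedily admitted; a candidate is removed when its identity estimate to any
already-kept genome of the species exceeds the threshold. Protected strains
are always kept and still serve as representatives, which means a
non-protected genome redundant only with a protected one is removed — the
protected genome stands in for it. Length-descending greedy order is a
proxy for "keep the genome providing the most unique sequence"; it
guarantees the longest genome of each species always survives and makes
dereplication idempotent.

## Community simulation

The simulator emulates a defined mixture of strains sequenced as 100 bp
paired-end reads. A fragment's source sequence is drawn with probability
proportional to concentration × sequence length — abundance is DNA-mass
proportional because shotgun sequencing samples base pairs, not cells; any
monotone weighting preserves the rank comparisons downstream evaluation
uses. Fragment starts are uniform; insert length is uniform in a configured
range (default 180–250 bp, so mates overlap by up to 20 bp); the two mates
read the fragment ends in forward/reverse orientation, with the fragment
strand flipped with probability ½. Substitution errors are i.i.d. per base
and never reproduce the original base. Quality strings are constant 'I'
(Phred 40) since nothing downstream consumes qualities. Every read gets a
truth row (strain, sequence, 0-based start of its own span, strand);
identical seeds give byte-identical FASTQ and truth files.

Not modelled: indels in reads, quality-dependent error profiles, GC or
platform bias, non-uniform fragment size distributions. Consequently the
benchmark exercises the *logic* of the pipeline (filters, tie handling,
coverage accounting) under controlled divergence, not the error structure
of any particular instrument.

`inject_low_complexity` replaces a seeded `round(fraction·n)` subset of
reads with homopolymer or dinucleotide repeats, providing screening-module
fixtures with known contamination rates.

## Low-complexity screening

The screen implements the classic DUST trinucleotide statistic: for every
length-64 window (shorter reads use one full-read window) the score is
S = Σ<sub>t</sub> c<sub>t</sub>(c<sub>t</sub>−1)/2 / (L−1), with
c<sub>t</sub> the count of each overlapping triplet and L the number of
counted triplets. Windows with S > 2.0 are masked wholesale and overlapping
masked windows merge; triplets containing N are not counted and N bases are
masked unconditionally. A read is removed when its masked fraction exceeds
0.5 (configurable — the removal criterion is this package's choice, the
original procedure specifies only that masked sequence is removed); a read
with no ACGT base at all is always removed, since it can never align. When
exactly one mate of a pair is removed the survivor moves to the fragment
set ("orphaning") and is mapped as a single read. Counts are conserved:
kept pairs × 2 + kept fragments + removed = input reads.

## Read mapping

The mapper indexes every forward-strand reference 16-mer below an
occupancy cutoff (default 1024; highly repetitive seeds are dropped) in
sorted arrays, and probes both read orientations at query time. Seed hits
vote for diagonals; diagonals closer than the band width cluster into one
candidate window per locus. Each window is extended with a local
dynamic-programming alignment (Gotoh recurrence in a numba kernel): match
+1, mismatch −2, first gap column −3, each further column −1. The window
spans the seeded diagonals plus a slack of ⌈read length × (1 −
min_similarity)⌉ + 2 on each side, which guarantees that no alignment able
to pass the identity filter is clipped — within that regime the banded
score equals the exhaustive full-matrix score, a property the test suite
asserts against an independent full-DP oracle.

Unaligned read ends become soft clips; the *length-fraction* filter (`-l`)
measures the aligned query fraction, and the *similarity* filter (`-s`)
measures matches over all alignment columns including gap columns. A
"100% length" setting therefore demands end-to-end alignment of the query.
All filter-passing placements tied at the maximal integer score form the
read's hit set; duplicate loci (same sequence, start, strand) are
collapsed. Tie resolution is deferred entirely to the resolution module.

Pairs are mapped mate-independently, then pairing information breaks ties:
if any combination of the mates' tied hits forms a proper pair (same
sequence, forward/reverse orientation with the forward hit on the left,
outer span within the insert range), tied hits not participating in any
proper combination are demoted. Whether an improper pair may outscore a
proper one is undocumented in the original tooling; this promote/demote
rule is the package's contract.

SAM import accepts any aligner's output whose references match the
database: records are grouped per read instance, scored by the AS tag when
present (otherwise rescored from CIGAR + NM), and only top-scoring
placements kept. SAM export is queryname-sorted so output bytes are
independent of processing order; tie-resolved reads get MAPQ 0,
tie-suppressed reads are written unmapped with a `ZS:Z:suppressed_multi`
tag.

## Resolution strategies

Given a hit set of n tied best placements: **top_random** reports one hit,
chosen uniformly by a generator keyed on (seed, read id) — hashing rather
than a stream RNG makes resolution independent of input order and of
parallel decomposition; **unique_only** reports the hit only when n = 1 and
otherwise suppresses the read; **topN** reports all n hits when n ≤ N
(default 5) and otherwise nothing; **all_hits** reports every tie. topN and
all_hits emit multiple placements per read, and downstream coverage counts
each emitted placement; fate classification takes such a read's best fate
and counts it as ambiguous separately.

## Coverage, detection and rollup

Per-base coverage is accumulated with difference arrays over the aligned
reference span [ref_start, ref_end) of every placed alignment — gap-aware
spans, not read lengths. Per strain (chromosome + plasmids): breadth =
100 × covered / length, depth = total coverage / length. Detection requires
breadth ≥ 1% *and* depth ≥ 0.01x; both thresholds are inclusive (the
source procedure states the cutoff without boundary semantics). Species and
genus rollups are unweighted arithmetic means over member strains in the
database — a deliberate choice over length weighting, matching how
multi-strain genera are conventionally averaged in this procedure — with
the member count reported per taxon. Relative abundance normalises taxon
depth over detected taxa. Whether per-genome depth should include plasmid
length is ambiguous in the source procedure; strain length as used is
logged in every row so either convention is recomputable.

## Evaluation

Fate classification assigns each truth-labelled read exactly one of:
correct strain, correct at level (right species/genus, wrong strain), wrong
taxon, unmapped, suppressed multi-mapper; counts sum to the read total by
construction, and reads dropped before mapping (screening) count as
unmapped. Spearman rank correlation (tie-corrected, via scipy) compares
detected depths with true concentrations. The chi-square depth comparison
rescales profile b to profile a's total and refers
Σ(a−e)²/e to the upper tail with n−1 degrees of freedom; applying a
count statistic to depths is unusual but mirrors how concordance between
aligner profiles is conventionally scored in this procedure, and p ≥ 0.05
reads as "similar". The log-depth ratio table pairs log10 depths per taxon
between a reference and an amended run, reporting zero/missing depths as
missing rather than −∞.

## Problem sizes and numerical choices

Tests and the acceptance script run on synthetic genomes of 20–100 kb and
communities of 10³–10⁵ read pairs — sizes chosen so the full suite, the
exhaustive DP oracles and the per-base coverage oracles all run comfortably
on a single CPU while still exercising every code path at meaningful
coverage (0.3–240x spread across strains, mirroring realistic mock-community
depth ranges). The design does not preclude Gb-scale references (the index
is array-based and the mapper streams reads), but no attempt is made to
benchmark at that scale. Integer alignment scores make tie detection exact;
coverage and breadth/depth arithmetic is exact integer accumulation until
the final division.

## Known limitations

- The mapper's sensitivity at high divergence is seed-limited: below ~80%
  identity, reads increasingly lack an intact 16-mer and go unmapped even
  when an alignment passing the filters exists. This mirrors real
  seed-and-extend aligners but is not calibrated to any specific one.
- Two co-optimal placements closer than one band width collapse into a
  single candidate window and only one is reported.
- The simulator's uniform, error-i.i.d. model means truth-recovery rates
  here are upper bounds on what real data would show; results on synthetic
  communities demonstrate correctness of the accounting, not field
  accuracy.
- Chi-square p-values on depth vectors inherit the usual caveat that
  depths are not counts; the statistic is a concordance score, not a
  calibrated test.
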