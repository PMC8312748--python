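# Methods

This note documents the models, algorithms and numerical choices behind
probeforge: a toolkit for designing custom target-enrichment probes in a
once-duplicated plant genome and for optimizing a universal probe
reference (Angiosperms353-style) toward a focal genome, together with the
locus-recovery and alignment statistics used to evaluate such probe sets.

## The biological setting

In a lineage that went through a whole-genome duplication (WGD), most
loci exist as paralog pairs; independent loss of different copies in
different sublineages ("one-duplicate loss") makes paralogs masquerade as
orthologs.  A custom probe set for such a group therefore targets (i)
single-copy loci, treated as potentially hidden paralogs, and (ii) loci
duplicated exactly once, while avoiding multigene families.  The design
cascade operationalizes this with explicit similarity thresholds: the
genome-wide average ortholog divergence between the focal genus and its
sister genus is about 3.65%, recent-WGD paralogs sit around 8%, so a 6%
minimum divergence between the copies of one locus separates true paralog
pairs from allelic or assembly noise.

## The built-in aligner

Every algorithm in the package consumes local-alignment hits in the BLAST
tabular (outfmt 6) vocabulary.  Hits can be imported from an external
tabular file, but the package also carries its own exact aligner so the
whole pipeline is testable without external binaries:

* affine-gap Smith–Waterman in the Gotoh formulation: match +2, mismatch
  −3, a gap of length L costs 5 + 2L (BLASTN-like);
* deterministic tie-breaks: best cell at the smallest (i, j); traceback
  prefers diagonal, then a gap consuming the subject, then one consuming
  the query; gaps prefer re-opening (shortest run);
* **X-dropoff path segmentation** (X = 40): the optimal path is cut
  wherever its running score falls more than X below its running maximum.
  This is the role X-dropoff plays in seeded aligners — without it a
  high-scoring alignment happily bridges an intron as a long gap (or a
  chain of gaps), because flanking exon score can always pay the
  crossing; with it, hits over a multi-exon locus come out exon-wise,
  matching how practitioners read BLAST output;
* multiple hits per pair by iterating: report the X-drop segments of the
  best path that clear the score threshold, mask the explored subject
  span, repeat until the best score falls below threshold;
* for genome-sized subjects an 11-mer two-seed scan selects candidate
  windows (diagonal bands containing at least two seeds, padded by 300
  bp) and the DP runs only inside them; `word_size=0` forces exhaustive
  DP, which is the mode compared against a brute-force oracle in the
  tests;
* E-values use the Karlin–Altschul formula with K = 0.41, λ = 0.625.
  These constants are approximate for this scoring, so raw-score
  thresholds are the primary cutoff and E-values are reported for
  orientation.  N and other IUPAC ambiguity codes never match.

`percent_divergence(a, b)` is 100 minus the identity (matches / alignment
columns × 100) of the single best local alignment, without segmentation;
it is meant for exon concatenations and other colinear sequences.

## The design cascade

Stages and thresholds, in the order they run (openness as printed:
"exceeding" is strict, all other bounds inclusive):

1. initial hit filter: length > 70 bp, > 10% of the query, identity ≥ 80%;
2. clustering: hits grouped by (query, subject, strand), sorted by
   subject position; a gap > 10,000 bp starts a new locus;
3. queries hitting > 6 loci dropped;
4. refined per-locus filter: merged-interval query coverage ≥ 90%,
   alignment-length-weighted mean identity ≥ 90%, every hit ≥ 100 bp
   (the bait length), every inter-hit gap ≤ 1200 bp;
5. queries with > 2 surviving loci dropped;
6. two-locus queries kept only if their exon concatenations diverge ≥ 6%;
7. cross-genome validation: the query must survive 1–6 in both genomes
   with equal locus counts; loci are paired across genomes by lowest
   exon divergence (best reciprocal) and each pair must diverge ≤ 15%
   (the rule is applied to paralog pairs as well as single-copy loci —
   the consistent reading of a criterion stated for single-copy loci);
   exons < 80 bp are excluded from the targets, a locus surviving as long
   as one exon remains;
8. introns ≥ 80 bp join the targets;
9. the extracted target sequences are collapsed greedily at ≥ 95%
   identity (identity computed over the shorter sequence), processing
   sequences in descending length.  Collapse runs **within each genome**:
   the two genomes' versions of a locus (~96% identical at 3.65%
   divergence) are deliberately kept as alternative representatives, so a
   retained locus carries two representatives, one per genome.

Exon–intron boundaries are inferred from the hit layout: exons are the
merged hit subject intervals, introns the complementary gaps inside the
cluster span.  Coverage uses merged query intervals so overlapping hits
are not double-counted; "similarity of the sum of all hits" is the
length-weighted mean of hit identities, the BLAST summary convention.

A consequence of these semantics worth knowing: because the refined
filter requires every hit ≥ 100 bp and exons are hit intervals, a locus
whose exons are all shorter than 80 bp is eliminated by the hit-length
rule before the exon-length rule can bite; the exon-length rule matters
for multi-exon loci where only some exons are short.

Every query receives an audit row naming the stage and criterion that
eliminated it; identical inputs and configuration give byte-identical
output FASTA and audit files.

**Monotonicity caveat.** Tightening thresholds almost always shrinks the
retained set, and the test suite asserts this over randomized stricter
configurations around the defaults.  It is not a theorem: the initial hit
filter interacts with the locus-count limits, so in contrived cases a
stricter identity cutoff can rescue a formerly promiscuous query by
deleting some of its loci.  The property is checked in the regime where
the interaction does not invert, and the audit trail makes any real case
inspectable.

## Universal-reference optimization

The optimization replaces a universal probe set's many divergent
representatives per locus by a single, focal-genome-matched sequence:

1. all annotated exons of one or more focal genomes are concatenated into
   transcripts (biotype policy: protein-coding genes, long non-coding
   RNAs and pseudogenes including transcribed ones; all other RNA classes
   and organellar sequences excluded; genes without transcript children
   form one implicit transcript, which accommodates flat annotation
   dialects);
2. all representatives are searched against the transcripts; per locus
   the longest hit (ties: higher bit score, then representative id)
   nominates both the best representative and the best matching
   transcript — when several genomes are supplied, the globally longest
   hit wins;
3. the matched transcript is split into its annotated exons, the exons
   are searched back against the chosen representative, and only the
   longest hit per exon is kept;
4. each exon is trimmed to its hit's query interval and the
   representative to the hit's subject interval; segments are
   concatenated in transcription order, minus-orientation exon segments
   reverse-complemented so both concatenations are co-directional, with
   no separators.

The trimmed representative concatenations form the best-hit reference;
the trimmed genome concatenations form the group-optimized reference.
Both have exactly one record per retained locus; loci without hits are
excluded and reported.  Re-running the optimization on its own best-hit
output with the same genome is a fixed point.

## Recovery statistics

`load_seq_lengths` reads the per-sample × per-locus recovered-length
table (first row locus ids, second row reference lengths — for
multi-representative loci the mean representative length — then one row
per sample).  Fractions recovered/target are capped at 1.0 because
assembled contigs can exceed the reference.  The threshold grid counts a
locus at (L, P) when the proportion of samples recovering at least
fraction L of the target is at least P; length thresholds {0.25, 0.50,
0.75} × presence thresholds {0.50, 0.75} by default.  Presence is
evaluated jointly at level L (the only reading under which the six grid
columns differ in both axes); an "any data" mode is available.
Enrichment efficiency is mapped/total reads × 100, consumed from a read
count table — read mapping itself is out of scope.

## Alignment statistics

The trim removes every row with more than 30% missing data (computed on
the original columns), then every column with more than 30% missing data
(computed on the retained rows) — one pass each, no fixpoint iteration,
which reproduces the R-based procedure this mirrors.  The order matters
and the operation is not idempotent in general: removing high-missing
columns can raise a surviving row's missing fraction.  Alignments with
fewer than four sequences are discarded.  Missing symbols are '-', '?'
and 'N'; other IUPAC ambiguity codes count as data for the trim and the
variability tally but are treated as missing when counting
parsimony-informative states (a conservative, AMAS-compatible choice).  A
column is constant when at most one distinct non-missing symbol remains,
parsimony-informative when at least two unambiguous bases each occur in
at least two sequences, otherwise a variable singleton.  Proportions are
kept at full precision internally and rounded half-up to one decimal only
in reports.

## The synthetic-data generator

The generator emulates the *inputs* of the cascade, not real genomes: a
pair of annotated genomes containing planted locus families, one scaffold
per locus copy (draft-assembly style), each copy flanked by neutral
spacers.  Defaults: 14 single-copy loci and 6 paralog pairs (20
qualifying loci), 2–3 exons of 160–300 bp per locus, introns 150–650 bp,
uniform base composition; ortholog divergence 3.65% (the genome-wide
average between the focal genus and its sister); a battery of 13 decoys,
each violating exactly one cascade criterion (hit length, query fraction,
identity, cluster gap, >6 loci, coverage, 100 bp hit, intron length,
>2 loci, <6% paralog divergence, summed identity, >15% ortholog
divergence, <80 bp exons), including a seven-copy multigene family.

Substitutions are site-independent and uniform over the three alternative
bases (Jukes–Cantor-like), with **exact counts**: round(p·L) distinct
interior positions per segment.  There are no indels by default, so
planted copies stay positionally comparable and the realized divergence
of every copy is known exactly.  Two guard mechanisms keep the planted
truth sharp: the first and last 12 bp of every exon are never mutated,
and the three intron/flank bases adjacent to each exon boundary are
forced to mismatch the query continuation, so local alignments neither
trim nor overrun exon bounds.  Real data are messier at exon edges; the
generator's claim is that the *decision logic* is exercised at exact,
controlled margins, not that capture data look like this.

Qualifying paralog pairs are planted at 6.2–7.0% divergence with a
reduced ortholog divergence of 2%.  This is a deliberate modelling
choice, fixed before any tuning: the cascade requires ≥ 6% between
paralogs and ≥ 90% identity between the query and the second genome, and
with additive divergences a pair at paralog divergence d survives the
second genome only when d + d_ortholog ≤ 10% — at the genome-wide average
of 3.65% the survivable window for pairs is a fraction of a percentage
point wide.  Biologically, WGD duplicates that are retained in pairs tend
to be dosage-constrained and evolve more slowly than the genome-wide
average, so giving retained pairs a lower ortholog rate is the realistic
way to obtain pairs that pass, and it documents exactly which pairs real
data would retain: the slowly-evolving tail.

The truth table derives each family's expected verdict mechanically from
the planted structure — position-wise mismatch counts stand in for
alignment identities (exact because the model is indel-free) and the
cascade's own thresholds are evaluated on those numbers.  Two decoys are
eliminated at an earlier stage than the criterion they were designed
around, necessarily so under the cascade's semantics: all-short-exon loci
die at the 100 bp hit rule, and a 25%-diverged ortholog dies at the
identity filters in the second genome before the explicit ≤ 15% check;
their retention verdicts are unaffected and the boundary rules themselves
are unit-tested on hand-built inputs.

Companion generators simulate recovered-length tables (per-cell dropout
plus a Beta-distributed recovered fraction; the truth grid is recomputed
by brute force) and alignment batches (columns planted as
constant/singleton/parsimony-informative, then missing data injected;
truth recomputed post-injection by exhaustive classification).

`evolve_ortholog_genome` applies rate-based per-site substitutions to
arbitrary genomes with coordinates preserved; the paired-genome builder
uses the exact-count machinery with the guard protections instead.

## Problem sizes and verification

All verification is desk-scale and runs on one CPU in minutes: ten
simulated genome pairs (~100 kb, 33 queries each) for planted-locus
recovery with zero tolerance for false positives or negatives; 200
random pairs up to 1 kb for the aligner-vs-oracle comparison (the oracle
is a separate, naive pure-Python DP with the same documented
tie-breaks); 50 random 20×50 matrices for the recovery grid; 1000
columns and 100 alignments for the alignment statistics; a hand-built
5-locus × 3-representative toy for the reference optimization, compared
byte-for-byte; 20 randomized stricter configurations for cascade
monotonicity.  `scripts/acceptance.py --seed N --out results.json`
recomputes all of these from scratch.

## Known limitations

* The engine is exact but not BLAST-bit-exact: word size, two-seed
  windowing and the Karlin–Altschul constants are approximations, so
  runs against real genomes will differ in borderline hits from a
  published BLAST-based design.
* The uniform substitution model has no rate heterogeneity, no indels
  and no repeats; conclusions about threshold behaviour transfer to real
  data, absolute recovery rates do not.
* Read processing, mapping, assembly and tree inference are out of
  scope; their outputs are consumed as files.
* Organellar exclusion is by sequence-id pattern, as annotations rarely
  flag it consistently.
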