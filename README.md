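# probeforge

Target-enrichment probe design and universal probe-set optimization for
plant groups with a recent whole-genome duplication (WGD), plus the
locus-recovery and alignment statistics used to evaluate such probe sets.

## The problem

Hybrid capture ("target enrichment") pulls a chosen set of loci out of a
genomic library with biotinylated baits.  In a WGD lineage, designing the
target set is the hard part: most loci exist as recent paralog pairs, and
independent copy loss makes paralogs masquerade as orthologs.  probeforge
implements, as one tested library and CLI:

* **the design cascade** — from self-genome similarity hits of a set of
  mRNA queries, find loci that are single-copy or duplicated exactly
  once, validate them against a second genome, infer exon–intron
  structure from the hit layout, and emit collapsed bait-target
  sequences.  The thresholds follow the published design of a Malinae
  (Rosaceae) probe set: hits > 70 bp, > 10% of the query, identity
  ≥ 80%; intron gaps ≤ 10 kb for locus assignment; ≥ 90% summed coverage
  and similarity per locus; hits ≥ 100 bp; introns ≤ 1200 bp; ≤ 2 loci
  per query with inter-locus divergence ≥ 6%; cross-genome exon
  divergence ≤ 15%; exons and targeted introns ≥ 80 bp; collapse at
  ≥ 95% identity;
* **reference optimization** — for a universal probe set with many
  divergent representatives per locus (Angiosperms353-style `taxon-locus`
  naming), pick the representative with the longest hit against the
  exon-concatenated transcripts of one or two annotated genomes, split
  the matched transcript into exons, trim both sides to the per-exon top
  hits and concatenate — yielding a "best-hit" reference (one trimmed
  original representative per locus) and a "group-optimized" reference
  (the focal-genome ortholog per locus);
* **recovery statistics** — per-sample × per-locus recovered-length
  fractions from HybPiper-style `seq_lengths` tables, enrichment
  efficiency, zero-data loci, and the locus-count grid over target-length
  × accessions-presence thresholds, with heatmap export;
* **alignment statistics** — the 30% row-then-column missing-data trim,
  the <4-sequence discard, and variable / parsimony-informative site
  counts (a site is parsimony-informative when ≥ 2 states each occur in
  ≥ 2 sequences);
* **a built-in exact local aligner** (affine-gap Smith–Waterman with
  X-dropoff path segmentation and 11-mer seeding) so everything above is
  testable without external binaries — precomputed BLAST outfmt 6 tables
  are accepted everywhere as an alternative;
* **a synthetic-data generator** that plants single-copy loci, paralog
  pairs at controlled divergence, multigene decoy families and
  per-criterion violation decoys in annotated genome pairs, with
  machine-readable truth tables.

See `docs/methods.md` for the models, tie-breaks and numerical choices.

## Worked example

Simulate an annotated genome pair with planted loci and run the design
cascade on it:

```bash
probeforge simulate genome --seed 5 --out sim/
probeforge design --genome-a sim/genome_A.fasta --genome-b sim/genome_B.fasta \
    --queries sim/queries.fasta --out design/
```

which prints

```
33 planted families; outputs in sim/
retained 52 loci (20 queries), 30308 exon bp; outputs in design/
```

(the exact base count varies with the seed).  Of the 33 simulated query
families, the 20 qualifying ones — 14 single-copy loci and 6 paralog
pairs, giving 52 target loci across copies and genomes — are retained and
the 13 decoys are rejected, each for the one criterion it was built to
violate; `design/audit.tsv` names the stage and criterion per query, e.g.

```
q_decoy_intron   refined_locus_filter   dropped   max_intron_len
q_decoy_lowdiv   interlocus_divergence  dropped   min_interlocus_divergence
q_pair_000       final                  retained
```

`design/targets_exons.fasta` holds the collapsed bait targets with
headers `>{paralog_group}|{locus}|exon{n}`, two representatives per locus
(one per genome).  The same library calls are available in Python:

```python
from probeforge import SimConfig, simulate_annotated_genome, design_probe_set

sim = simulate_annotated_genome(SimConfig(seed=5))
targets, audit = design_probe_set(sim.genome_a, sim.genome_b, sim.queries)
print(len(targets.loci), targets.total_exon_bp)   # 52 30308
```

Other subcommands: `probeforge extract-exons`, `probeforge search`,
`probeforge optimize-ref`, `probeforge recovery-stats`,
`probeforge aln-stats`, `probeforge simulate recovery|alignments`.

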