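"""Optimization of a universal probe reference toward a focal genome.

A universal probe set (Angiosperms353-style) carries several divergent
sequence representatives per locus.  For each locus this module:

1. searches all representatives against the exon-concatenated transcripts
   of one or more annotated genomes and keeps the longest hit (ties by bit
   score, then representative id) -- this nominates both the best
   representative and its best matching genome transcript;
2. splits the matched transcript into its annotated exons;
3. searches the exons back against the chosen representative and keeps the
   longest hit per exon;
4. trims each exon to its hit interval and the representative to the
   corresponding interval, and concatenates each side in transcription
   order.

The concatenated representative segments form the "best-hit" reference
(one original representative per locus, trimmed); the concatenated genome
segments form the "group-optimized" reference (the representative replaced
by the focal-genome ortholog).  Both end up with exactly one record per
retained locus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .seqio import (
    BiotypePolicy,
    SequenceRecord,
    TranscriptModel,
    extract_exon_transcripts,
    reverse_complement,
    write_fasta,
)
from .simsearch import Hit, SearchParams, local_search

__all__ = [
    "UniversalProbeSet",
    "OptimizedReference",
    "parse_universal_set",
    "best_representative_per_locus",
    "split_transcript_to_exons",
    "top_hit_per_exon",
    "trim_and_concatenate",
    "build_optimized_references",
]

# Angiosperms353 naming dialect: "<taxon>-<locusID>"
DEFAULT_LOCUS_REGEX = re.compile(r"^(?P<taxon>.+)-(?P<locus>[^-]+)$")


@dataclass
class UniversalProbeSet:
    """Representatives grouped by locus id."""

    loci: dict[str, list[SequenceRecord]]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def mean_representatives(self) -> float:
        return sum(len(v) for v in self.loci.values()) / max(len(self.loci), 1)


@dataclass
class OptimizedReference:
    """Per-locus outcome of the optimization."""

    entries: dict[str, dict] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)  # locus -> reason


def parse_universal_set(
    records: Sequence[SequenceRecord], locus_regex: re.Pattern = DEFAULT_LOCUS_REGEX
) -> UniversalProbeSet:
    """Group representative records by the locus tag in their names."""
    loci: dict[str, list[SequenceRecord]] = {}
    for r in records:
        m = locus_regex.match(r.id)
        if not m:
            raise ValueError(f"representative id {r.id!r} does not carry a locus tag")
        loci.setdefault(m.group("locus"), []).append(r)
    return UniversalProbeSet(loci)


def _hit_order_key(h: Hit):
    # longest hit first; ties by bit score, then lexicographic ids
    return (-h.align_length, -h.bit_score, h.query_id, h.subject_id, h.s_lo)


def best_representative_per_locus(
    hits: Sequence[Hit], universal: UniversalProbeSet
) -> tuple[dict[str, tuple[str, str, Hit]], dict[str, str]]:
    """Per locus, the representative/transcript pair with the longest hit.

    Returns (locus -> (rep_id, transcript_id, top hit), report of loci
    without hits)."""
    rep_locus = {
        r.id: locus for locus, reps in universal.loci.items() for r in reps
    }
    best: dict[str, Hit] = {}
    for h in sorted(hits, key=_hit_order_key):
        locus = rep_locus.get(h.query_id)
        if locus is None or locus in best:
            continue
        best[locus] = h
    chosen = {
        locus: (h.query_id, h.subject_id, h) for locus, h in best.items()
    }
    missing = {
        locus: "no_hits" for locus in universal.loci if locus not in chosen
    }
    return chosen, missing


def split_transcript_to_exons(tm: TranscriptModel) -> list[SequenceRecord]:
    """One record per exon, ids ``{transcript_id}.exon{n}`` in transcription
    order; the concatenation of the records equals the transcript."""
    out = []
    offset = 0
    for n, (start, end) in enumerate(tm.exons, 1):
        length = end - start + 1
        out.append(
            SequenceRecord(
                f"{tm.transcript_id}.exon{n}",
                tm.concatenated_seq[offset : offset + length],
            )
        )
        offset += length
    return out


def top_hit_per_exon(hits: Sequence[Hit]) -> dict[str, Hit]:
    """Longest hit per exon (queries are exons); exons without hits absent."""
    best: dict[str, Hit] = {}
    for h in sorted(hits, key=_hit_order_key):
        if h.query_id not in best:
            best[h.query_id] = h
    return best


def trim_and_concatenate(
    chosen_rep: SequenceRecord,
    exon_records: Sequence[SequenceRecord],
    per_exon_hits: dict[str, Hit],
) -> tuple[str, str]:
    """Trim exons and representative to the top-hit bounds and concatenate.

    For each exon (in transcription order) with a hit, the exon is cut to
    the hit's query interval and the representative to the hit's subject
    interval; minus-orientation hits reverse complement the exon segment so
    the two concatenations are co-directional.  Returns
    ``(trimmed_probe_seq, trimmed_genome_seq)``.
    """
    probe_parts: list[str] = []
    genome_parts: list[str] = []
    for exon in exon_records:
        h = per_exon_hits.get(exon.id)
        if h is None:
            continue
        if h.q_end > len(exon.seq) or h.s_hi > len(chosen_rep.seq):
            raise ValueError(f"hit coordinates out of bounds for exon {exon.id!r}")
        exon_seg = exon.seq[h.q_start - 1 : h.q_end]
        rep_seg = chosen_rep.seq[h.s_lo - 1 : h.s_hi]
        if h.strand == "-":
            exon_seg = reverse_complement(exon_seg)
        probe_parts.append(rep_seg)
        genome_parts.append(exon_seg)
    return "".join(probe_parts), "".join(genome_parts)


def build_optimized_references(
    universal: UniversalProbeSet | Sequence[SequenceRecord],
    genomes: Sequence[tuple[str, Sequence, Sequence]],
    params: SearchParams | None = None,
    policy: BiotypePolicy | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], OptimizedReference]:
    """Build the best-hit and group-optimized references.

    ``genomes`` is a sequence of ``(label, genome_records, gff_features)``
    tuples; transcripts from all genomes compete and the globally longest
    hit nominates the matched transcript.  Returns (bestHit reference,
    group-optimized reference, detailed report).
    """
    params = params or SearchParams()
    if not isinstance(universal, UniversalProbeSet):
        universal = parse_universal_set(universal)

    transcripts: dict[str, TranscriptModel] = {}
    subjects: list[SequenceRecord] = []
    for label, genome, feats in genomes:
        for tm in extract_exon_transcripts(genome, feats, policy):
            tid = f"{label}:{tm.transcript_id}"
            tm.transcript_id = tid
            transcripts[tid] = tm
            subjects.append(SequenceRecord(tid, tm.concatenated_seq))

    reps = [r for recs in universal.loci.values() for r in recs]
    hits = local_search(reps, subjects, params)
    chosen, missing = best_representative_per_locus(hits, universal)

    rep_by_id = {r.id: r for r in reps}
    best_ref: list[SequenceRecord] = []
    group_ref: list[SequenceRecord] = []
    result = OptimizedReference(skipped=dict(missing))

    for locus in sorted(universal.loci):
        if locus not in chosen:
            continue
        rep_id, tid, top = chosen[locus]
        rep = rep_by_id[rep_id]
        tm = transcripts[tid]
        exon_records = split_transcript_to_exons(tm)
        exon_hits_all = local_search(exon_records, [rep], params)
        exon_hits = top_hit_per_exon(exon_hits_all)
        probe_seq, genome_seq = trim_and_concatenate(rep, exon_records, exon_hits)
        if not probe_seq or not genome_seq:
            result.skipped[locus] = "no_exon_hits"
            continue
        best_ref.append(SequenceRecord(locus, probe_seq))
        group_ref.append(SequenceRecord(locus, genome_seq))
        result.entries[locus] = {
            "chosen_representative_id": rep_id,
            "matched_genome_transcript_id": tid,
            "trimmed_probe_seq": probe_seq,
            "trimmed_genome_seq": genome_seq,
            "per_exon_hit_bounds": {
                eid: (h.q_start, h.q_end, h.s_start, h.s_end)
                for eid, h in sorted(exon_hits.items())
            },
            "n_exons_kept": len(exon_hits),
        }
    return best_ref, group_ref, result


def write_refopt_outputs(
    best_ref: Sequence[SequenceRecord],
    group_ref: Sequence[SequenceRecord],
    result: OptimizedReference,
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(best_ref, outdir / "bestHit_modified.fasta")
    write_fasta(group_ref, outdir / "group_optimized.fasta")
    with open(outdir / "refopt_report.tsv", "w") as fh:
        fh.write("locus\tchosen_rep\ttranscript\tn_exons_kept\ttotal_bp\n")
        for locus in sorted(result.entries):
            e = result.entries[locus]
            fh.write(
                f"{locus}\t{e['chosen_representative_id']}\t"
                f"{e['matched_genome_transcript_id']}\t{e['n_exons_kept']}\t"
                f"{len(e['trimmed_genome_seq'])}\n"
            )
        for locus in sorted(result.skipped):
            fh.write(f"{locus}\t-\t-\t0\t0\t# {result.skipped[locus]}\n")
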