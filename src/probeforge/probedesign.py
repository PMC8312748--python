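"""The custom-probe design cascade.

Given self-genome similarity hits for a set of mRNA queries, the cascade
identifies loci that are single-copy or duplicated exactly once in the
genome, validates them against a second genome, infers exon-intron
structure from the hit layout, and emits collapsed bait-target sequences.

Stages, in order:

1. initial hit filter     - hit length > 70 bp, > 10% of query, identity >= 80%
2. clustering             - hits on one subject grouped into loci; a gap
                            > 10,000 bp between consecutive hits starts a
                            new locus
3. initial count filter   - queries hitting more than 6 loci dropped
4. refined locus filter   - summed query coverage >= 90%, length-weighted
                            identity >= 90%, every hit >= 100 bp, every
                            inter-hit gap (intron) <= 1200 bp
5. refined count filter   - queries with more than 2 surviving loci dropped
6. inter-locus divergence - two-locus queries kept only if their exon
                            concatenations diverge by >= 6%
7. cross-genome validation- query must survive 1-6 in both genomes with
                            equal locus counts; matched loci must diverge
                            by <= 15% on their exons; exons < 80 bp are
                            excluded from the targets
8. intron selection       - introns >= 80 bp kept as additional targets
9. collapse               - extracted sequences collapsed at >= 95% identity

Comparison openness follows the printed thresholds: "exceeding" is strict
(>), every other bound is inclusive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import SequenceRecord, reverse_complement, write_fasta
from .simsearch import Hit, SearchParams, local_search, percent_divergence

__all__ = [
    "DesignConfig",
    "LocusCluster",
    "ProbeLocus",
    "ProbeTargetSet",
    "QueryReport",
    "initial_hit_filter",
    "cluster_hits_to_loci",
    "drop_promiscuous_queries",
    "refined_locus_filter",
    "interlocus_divergence_filter",
    "cross_genome_validate",
    "extract_locus_sequence",
    "infer_exon_intron_boundaries",
    "select_intron_targets",
    "collapse_sequences",
    "run_cascade",
    "design_probe_set",
]


@dataclass(frozen=True)
class DesignConfig:
    """Numeric thresholds of the design cascade.

    Openness of each comparison: ``min_hit_len`` and ``min_hit_query_frac``
    are strict (a hit must *exceed* 70 bp and 10% of the query); all other
    bounds are inclusive as printed (>= / <=).
    """

    min_hit_len: int = 70                 # hit length must exceed this
    min_hit_query_frac: float = 0.10      # hit length must exceed frac * query length
    min_hit_identity: float = 80.0        # >=
    max_cluster_gap: int = 10_000         # <= between consecutive hits of one locus
    max_loci_per_query_initial: int = 6   # queries with more loci dropped
    min_sum_coverage: float = 90.0        # >= percent of query covered by merged hits
    min_sum_identity: float = 90.0        # >= length-weighted mean hit identity
    min_single_hit_len: int = 100         # >= every hit
    max_intron_len: int = 1200            # <= every inter-hit subject gap
    max_loci_per_query: int = 2
    min_interlocus_divergence: float = 6.0   # >= between exon concatenations
    max_ortholog_divergence: float = 15.0    # <= between the two genomes' exons
    min_exon_len: int = 80                # >= for an exon to stay in the targets
    collapse_identity: float = 95.0       # >= for greedy collapse
    min_intron_target_len: int = 80       # >= for an intron to become a target

    def __post_init__(self) -> None:
        for name in ("min_sum_coverage", "min_sum_identity", "collapse_identity"):
            if not 0 < getattr(self, name) <= 100:
                raise ValueError(f"{name} must be in (0, 100]")


@dataclass
class LocusCluster:
    """An ordered group of hits on one subject region: one candidate locus."""

    query_id: str
    subject_id: str
    strand: str
    hits: list[Hit]
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)
    intron_intervals: list[tuple[int, int]] = field(default_factory=list)
    sum_coverage_frac: float = 0.0
    weighted_identity: float = 0.0
    exon_seq: str = ""   # concatenated exon sequence, transcription order

    @property
    def span(self) -> tuple[int, int]:
        return (min(h.s_lo for h in self.hits), max(h.s_hi for h in self.hits))


@dataclass
class ProbeLocus:
    locus_id: str
    paralog_group_id: str
    source_query_id: str
    genome_label: str
    exon_seqs: list[str]
    intron_seqs: list[str]
    copy_number: int


@dataclass
class ProbeTargetSet:
    loci: list[ProbeLocus]
    provenance: dict
    total_exon_bp: int = 0

    def recompute_total(self) -> int:
        self.total_exon_bp = sum(len(e) for l in self.loci for e in l.exon_seqs)
        return self.total_exon_bp


@dataclass
class QueryReport:
    """Cascade outcome for one query in one genome."""

    query_id: str
    clusters: list[LocusCluster]
    passed: bool
    stage: str               # last stage evaluated
    failing_criterion: str   # "" when passed


# ---------------------------------------------------------------- filtering


def initial_hit_filter(
    hits: Iterable[Hit], query_lengths: dict[str, int], cfg: DesignConfig
) -> list[Hit]:
    """Keep hits exceeding 70 bp and 10% of the query length with >= 80%
    identity."""
    out = []
    for h in hits:
        if h.query_id not in query_lengths:
            raise KeyError(f"unknown query id {h.query_id!r}")
        qlen = query_lengths[h.query_id]
        if (
            h.align_length > cfg.min_hit_len
            and h.align_length > cfg.min_hit_query_frac * qlen
            and h.percent_identity >= cfg.min_hit_identity
        ):
            out.append(h)
    return out


def cluster_hits_to_loci(hits: Iterable[Hit], cfg: DesignConfig) -> list[LocusCluster]:
    """Group hits into candidate loci.

    Hits are grouped by (query, subject, strand) and sorted by subject
    coordinate; a gap of more than ``max_cluster_gap`` bases between
    consecutive hits starts a new cluster.
    """
    groups: dict[tuple[str, str, str], list[Hit]] = {}
    for h in hits:
        groups.setdefault((h.query_id, h.subject_id, h.strand), []).append(h)
    clusters: list[LocusCluster] = []
    for (qid, sid, strand), grp in sorted(groups.items()):
        grp.sort(key=lambda h: (h.s_lo, h.s_hi))
        current = [grp[0]]
        for h in grp[1:]:
            gap = h.s_lo - max(x.s_hi for x in current) - 1
            if gap > cfg.max_cluster_gap:
                clusters.append(LocusCluster(qid, sid, strand, current))
                current = [h]
            else:
                current.append(h)
        clusters.append(LocusCluster(qid, sid, strand, current))
    return clusters


def drop_promiscuous_queries(
    clusters: Sequence[LocusCluster], cfg: DesignConfig, stage: str
) -> tuple[list[LocusCluster], set[str]]:
    """Remove all clusters of queries with too many loci.

    ``stage='initial'`` applies the >6 rule, ``stage='refined'`` the >2
    rule.  Returns surviving clusters and the set of dropped query ids.
    """
    limit = {
        "initial": cfg.max_loci_per_query_initial,
        "refined": cfg.max_loci_per_query,
    }[stage]
    counts: dict[str, int] = {}
    for c in clusters:
        counts[c.query_id] = counts.get(c.query_id, 0) + 1
    dropped = {q for q, n in counts.items() if n > limit}
    return [c for c in clusters if c.query_id not in dropped], dropped


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for lo, hi in sorted(ivals):
        if out and lo <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def refined_locus_filter(
    cluster: LocusCluster, query_length: int, cfg: DesignConfig
) -> tuple[bool, list[str]]:
    """Evaluate the refined per-locus criteria; returns (pass, failed flags).

    Coverage is computed on merged query intervals so overlapping hits are
    not double counted; summed identity is the alignment-length-weighted
    mean of hit identities.
    """
    flags: list[str] = []
    merged_q = _merge_intervals([(h.q_start, h.q_end) for h in cluster.hits])
    covered = sum(hi - lo + 1 for lo, hi in merged_q)
    cluster.sum_coverage_frac = 100.0 * covered / query_length
    total = sum(h.align_length for h in cluster.hits)
    cluster.weighted_identity = (
        sum(h.percent_identity * h.align_length for h in cluster.hits) / total
    )
    if cluster.sum_coverage_frac < cfg.min_sum_coverage:
        flags.append("min_sum_coverage")
    if cluster.weighted_identity < cfg.min_sum_identity:
        flags.append("min_sum_identity")
    if any(h.align_length < cfg.min_single_hit_len for h in cluster.hits):
        flags.append("min_single_hit_len")
    s_merged = _merge_intervals([(h.s_lo, h.s_hi) for h in cluster.hits])
    for (lo1, hi1), (lo2, hi2) in zip(s_merged, s_merged[1:]):
        if lo2 - hi1 - 1 > cfg.max_intron_len:
            flags.append("max_intron_len")
            break
    return not flags, flags


def infer_exon_intron_boundaries(
    cluster: LocusCluster,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Exons are the merged hit subject intervals; introns the complementary
    gaps between consecutive exons inside the cluster span."""
    exons = _merge_intervals([(h.s_lo, h.s_hi) for h in cluster.hits])
    introns = [
        (hi1 + 1, lo2 - 1)
        for (lo1, hi1), (lo2, hi2) in zip(exons, exons[1:])
        if lo2 - hi1 > 1
    ]
    cluster.exon_intervals = exons
    cluster.intron_intervals = introns
    return exons, introns


def extract_locus_sequence(
    genome: dict[str, str] | Sequence[SequenceRecord], cluster: LocusCluster
) -> str:
    """Genomic substring spanning the cluster (introns included);
    minus-strand loci are reverse complemented."""
    seqs = genome if isinstance(genome, dict) else {r.id: r.seq for r in genome}
    lo, hi = cluster.span
    seq = seqs[cluster.subject_id][lo - 1 : hi]
    return reverse_complement(seq) if cluster.strand == "-" else seq


def _exon_concat(genome_seqs: dict[str, str], cluster: LocusCluster) -> str:
    if not cluster.exon_intervals:
        infer_exon_intron_boundaries(cluster)
    chrom = genome_seqs[cluster.subject_id]
    parts = [chrom[lo - 1 : hi] for lo, hi in cluster.exon_intervals]
    concat = "".join(parts)
    if cluster.strand == "-":
        concat = reverse_complement(concat)
    cluster.exon_seq = concat
    return concat


def interlocus_divergence_filter(
    loci_of_query: Sequence[LocusCluster],
    cfg: DesignConfig,
    search_params: SearchParams | None = None,
) -> bool:
    """Single-locus queries pass; two-locus queries pass only if the exon
    concatenations of the two loci diverge by at least the threshold."""
    if len(loci_of_query) <= 1:
        return True
    a, b = loci_of_query[0].exon_seq, loci_of_query[1].exon_seq
    div, _ = percent_divergence(a, b, search_params)
    return div >= cfg.min_interlocus_divergence


# ---------------------------------------------------------------- cascade


def run_cascade(
    hits: Sequence[Hit],
    queries: Sequence[SequenceRecord],
    genome: Sequence[SequenceRecord],
    cfg: DesignConfig | None = None,
    search_params: SearchParams | None = None,
) -> dict[str, QueryReport]:
    """Run stages 1-6 for one genome; returns a report per query that had
    at least one raw hit."""
    cfg = cfg or DesignConfig()
    qlens = {q.id: len(q.seq) for q in queries}
    gseqs = {r.id: r.seq for r in genome}
    reports: dict[str, QueryReport] = {}

    kept = initial_hit_filter(hits, qlens, cfg)
    raw_queries = {h.query_id for h in hits}
    for qid in sorted(raw_queries - {h.query_id for h in kept}):
        reports[qid] = QueryReport(qid, [], False, "initial_hit_filter", "no_passing_hits")

    clusters = cluster_hits_to_loci(kept, cfg)
    clusters, dropped = drop_promiscuous_queries(clusters, cfg, "initial")
    for qid in sorted(dropped):
        reports[qid] = QueryReport(qid, [], False, "initial_count_filter", "max_loci_per_query_initial")

    by_query: dict[str, list[LocusCluster]] = {}
    for c in clusters:
        by_query.setdefault(c.query_id, []).append(c)

    refined_clusters: list[LocusCluster] = []
    for qid, cls in sorted(by_query.items()):
        surviving = []
        fail_flags: list[str] = []
        for c in cls:
            ok, flags = refined_locus_filter(c, qlens[qid], cfg)
            if ok:
                surviving.append(c)
            else:
                fail_flags.extend(flags)
        if not surviving:
            reports[qid] = QueryReport(qid, [], False, "refined_locus_filter",
                                       ",".join(sorted(set(fail_flags))))
        else:
            by_query[qid] = surviving
            refined_clusters.extend(surviving)

    refined_clusters, dropped = drop_promiscuous_queries(refined_clusters, cfg, "refined")
    for qid in sorted(dropped):
        reports[qid] = QueryReport(qid, [], False, "refined_count_filter", "max_loci_per_query")

    final_by_query: dict[str, list[LocusCluster]] = {}
    for c in refined_clusters:
        final_by_query.setdefault(c.query_id, []).append(c)

    for qid, cls in sorted(final_by_query.items()):
        for c in cls:
            infer_exon_intron_boundaries(c)
            _exon_concat(gseqs, c)
        if interlocus_divergence_filter(cls, cfg, search_params):
            reports[qid] = QueryReport(qid, cls, True, "interlocus_divergence", "")
        else:
            reports[qid] = QueryReport(qid, [], False, "interlocus_divergence",
                                       "min_interlocus_divergence")
    return reports


def _pair_loci_across_genomes(
    loci_a: list[LocusCluster],
    loci_b: list[LocusCluster],
    search_params: SearchParams | None,
) -> list[tuple[LocusCluster, LocusCluster, float]]:
    """Match per-query loci of the two genomes by lowest exon divergence
    (best reciprocal pairing)."""
    if len(loci_a) == 1 and len(loci_b) == 1:
        d, _ = percent_divergence(loci_a[0].exon_seq, loci_b[0].exon_seq, search_params)
        return [(loci_a[0], loci_b[0], d)]
    divs = {}
    for i, ca in enumerate(loci_a):
        for j, cb in enumerate(loci_b):
            divs[(i, j)], _ = percent_divergence(ca.exon_seq, cb.exon_seq, search_params)
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for (i, j), d in sorted(divs.items(), key=lambda kv: (kv[1], kv[0])):
        if i not in used_a and j not in used_b:
            pairs.append((loci_a[i], loci_b[j], d))
            used_a.add(i)
            used_b.add(j)
    return pairs


def cross_genome_validate(
    report_a: dict[str, QueryReport],
    report_b: dict[str, QueryReport],
    cfg: DesignConfig | None = None,
    search_params: SearchParams | None = None,
) -> dict[str, dict]:
    """Stage 7: keep queries that survived in both genomes with equal locus
    counts and acceptable inter-genome exon divergence.

    Returns per retained query: matched locus pairs and audit info for
    dropped queries under key ``"_dropped"``.
    """
    cfg = cfg or DesignConfig()
    retained: dict[str, dict] = {}
    dropped: dict[str, str] = {}
    all_qids = sorted(set(report_a) | set(report_b))
    for qid in all_qids:
        ra, rb = report_a.get(qid), report_b.get(qid)
        if ra is None or rb is None or not ra.passed or not rb.passed:
            if (ra and ra.passed) or (rb and rb.passed):
                dropped[qid] = "absent_or_failed_in_other_genome"
            continue
        if len(ra.clusters) != len(rb.clusters):
            dropped[qid] = "unequal_locus_counts"
            continue
        pairs = _pair_loci_across_genomes(ra.clusters, rb.clusters, search_params)
        if any(d > cfg.max_ortholog_divergence for _, _, d in pairs):
            dropped[qid] = "max_ortholog_divergence"
            continue
        retained[qid] = {"pairs": pairs, "copy_number": len(ra.clusters)}
    retained["_dropped"] = dropped  # type: ignore[assignment]
    return retained


def select_intron_targets(loci: Sequence[ProbeLocus], cfg: DesignConfig) -> list[ProbeLocus]:
    """Drop introns below the bait-design length floor; exons untouched."""
    for l in loci:
        l.intron_seqs = [s for s in l.intron_seqs if len(s) >= cfg.min_intron_target_len]
    return list(loci)


def collapse_sequences(
    seqs: Sequence[SequenceRecord],
    cfg: DesignConfig | None = None,
    search_params: SearchParams | None = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy collapse at >= 95% identity.

    Sequences are processed in descending length (ties by id); each joins
    the first existing cluster whose representative matches it at >= the
    collapse identity computed over the shorter sequence, else founds a new
    cluster.  Returns representatives in founding order and a member ->
    representative map.
    """
    if not seqs:
        raise ValueError("no sequences to collapse")
    cfg = cfg or DesignConfig()
    from .simsearch import best_local_alignment

    def kmers(s: str, k: int = 8) -> set[str]:
        return {s[i : i + k] for i in range(len(s) - k + 1)}

    reps: list[SequenceRecord] = []
    rep_kmers: dict[str, set[str]] = {}
    membership: dict[str, str] = {}
    for rec in sorted(seqs, key=lambda r: (-len(r.seq), r.id)):
        placed = False
        rec_kmers = kmers(rec.seq)
        for rep in reps:
            # near-identical sequences necessarily share 8-mers; skip the
            # alignment when none are shared
            if not (rep_kmers[rep.id] & rec_kmers):
                continue
            tb = best_local_alignment(rep.seq, rec.seq, search_params)
            if tb is None:
                continue
            shorter = min(len(rep.seq), len(rec.seq))
            ident = 100.0 * tb["matches"] / shorter
            if ident >= cfg.collapse_identity:
                membership[rec.id] = rep.id
                placed = True
                break
        if not placed:
            reps.append(rec)
            rep_kmers[rec.id] = rec_kmers
            membership[rec.id] = rec.id
    return reps, membership


# ------------------------------------------------------------ orchestration


def _digest(records: Sequence[SequenceRecord]) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(r.id.encode())
        h.update(r.seq.encode())
    return h.hexdigest()[:16]


def design_probe_set(
    genome_a: Sequence[SequenceRecord],
    genome_b: Sequence[SequenceRecord],
    queries: Sequence[SequenceRecord],
    cfg: DesignConfig | None = None,
    search_params: SearchParams | None = None,
    hits_a: Sequence[Hit] | None = None,
    hits_b: Sequence[Hit] | None = None,
    genome_labels: tuple[str, str] = ("A", "B"),
) -> tuple[ProbeTargetSet, list[dict]]:
    """Run the full design cascade on a genome pair.

    Precomputed hit tables may be supplied; otherwise the built-in engine
    searches the queries against each genome.  Returns the target set and
    an audit table (one row per query and stage outcome).
    """
    cfg = cfg or DesignConfig()
    audit: list[dict] = []
    if not queries:
        return ProbeTargetSet([], {"note": "empty query set"}, 0), audit

    sp = search_params or SearchParams()
    if hits_a is None:
        hits_a = local_search(queries, genome_a, sp)
    if hits_b is None:
        hits_b = local_search(queries, genome_b, sp)

    rep_a = run_cascade(hits_a, queries, genome_a, cfg, sp)
    rep_b = run_cascade(hits_b, queries, genome_b, cfg, sp)
    validated = cross_genome_validate(rep_a, rep_b, cfg, sp)
    dropped_cross = validated.pop("_dropped")

    gseqs = {
        genome_labels[0]: {r.id: r.seq for r in genome_a},
        genome_labels[1]: {r.id: r.seq for r in genome_b},
    }

    loci: list[ProbeLocus] = []
    for qid in sorted(k for k in validated):
        info = validated[qid]
        copy_number = info["copy_number"]
        locus_ok = True
        built: list[ProbeLocus] = []
        for k, (ca, cb, _div) in enumerate(info["pairs"], 1):
            for label, cluster in ((genome_labels[0], ca), (genome_labels[1], cb)):
                chrom = gseqs[label][cluster.subject_id]
                exon_seqs = [chrom[lo - 1 : hi] for lo, hi in cluster.exon_intervals]
                intron_seqs = [chrom[lo - 1 : hi] for lo, hi in cluster.intron_intervals]
                if cluster.strand == "-":
                    exon_seqs = [reverse_complement(s) for s in reversed(exon_seqs)]
                    intron_seqs = [reverse_complement(s) for s in reversed(intron_seqs)]
                exon_seqs = [s for s in exon_seqs if len(s) >= cfg.min_exon_len]
                if not exon_seqs:
                    locus_ok = False
                    continue
                built.append(
                    ProbeLocus(
                        locus_id=f"{qid}|{label}|locus{k}",
                        paralog_group_id=f"{qid}@{label}",
                        source_query_id=qid,
                        genome_label=label,
                        exon_seqs=exon_seqs,
                        intron_seqs=intron_seqs,
                        copy_number=copy_number,
                    )
                )
        if not locus_ok and not built:
            dropped_cross[qid] = "min_exon_len"
            continue
        loci.extend(built)
        audit.append({"query_id": qid, "stage": "final", "verdict": "retained",
                      "failing_criterion": ""})

    for qid, reason in sorted(dropped_cross.items()):
        audit.append({"query_id": qid, "stage": "cross_genome_validate",
                      "verdict": "dropped", "failing_criterion": reason})
    for rep in (rep_a, rep_b):
        for qid, r in sorted(rep.items()):
            if not r.passed:
                row = {"query_id": qid, "stage": r.stage, "verdict": "dropped",
                       "failing_criterion": r.failing_criterion}
                if row not in audit:
                    audit.append(row)
    audit.sort(key=lambda row: (row["query_id"], row["stage"]))

    select_intron_targets(loci, cfg)

    # collapse the extracted target sequences at >= 95% identity, within
    # each genome: the two genomes' versions of a locus are kept as
    # alternative representatives (two per locus, like the published set)
    membership: dict[str, str] = {}
    for label in genome_labels:
        exon_records = [
            SequenceRecord(f"{l.paralog_group_id}|{l.locus_id}|exon{i+1}", s)
            for l in loci
            if l.genome_label == label
            for i, s in enumerate(l.exon_seqs)
        ]
        if not exon_records:
            continue
        reps, member = collapse_sequences(exon_records, cfg, sp)
        membership.update(member)
        keep_ids = {r.id for r in reps}
        for l in loci:
            if l.genome_label != label:
                continue
            l.exon_seqs = [
                s for i, s in enumerate(l.exon_seqs)
                if f"{l.paralog_group_id}|{l.locus_id}|exon{i+1}" in keep_ids
            ]
    loci = [l for l in loci if l.exon_seqs]

    provenance = {
        "config": asdict(cfg),
        "genome_digests": {genome_labels[0]: _digest(genome_a),
                           genome_labels[1]: _digest(genome_b)},
        "query_digest": _digest(queries),
        "collapse_membership": membership,
    }
    tset = ProbeTargetSet(loci, provenance)
    tset.recompute_total()
    return tset, audit


def retained_query_ids(target_set: ProbeTargetSet) -> set[str]:
    return {l.source_query_id for l in target_set.loci}


def write_design_outputs(
    target_set: ProbeTargetSet, audit: list[dict], outdir: str | Path
) -> None:
    """Write targets_exons.fasta, targets_introns.fasta, audit.tsv and
    provenance.json (deterministic byte-for-byte for identical inputs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exons = [
        SequenceRecord(f"{l.paralog_group_id}|{l.locus_id}|exon{i+1}", s)
        for l in target_set.loci
        for i, s in enumerate(l.exon_seqs)
    ]
    introns = [
        SequenceRecord(f"{l.paralog_group_id}|{l.locus_id}|intron{i+1}", s)
        for l in target_set.loci
        for i, s in enumerate(l.intron_seqs)
    ]
    write_fasta(exons, outdir / "targets_exons.fasta")
    write_fasta(introns, outdir / "targets_introns.fasta")
    with open(outdir / "audit.tsv", "w") as fh:
        fh.write("query_id\tstage\tverdict\tfailing_criterion\n")
        for row in audit:
            fh.write(f"{row['query_id']}\t{row['stage']}\t{row['verdict']}\t"
                     f"{row['failing_criterion']}\n")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(target_set.provenance | {"total_exon_bp": target_set.total_exon_bp},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
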