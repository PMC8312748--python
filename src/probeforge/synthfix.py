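"""Synthetic annotated genomes and companion tables for desk-scale testing.

The generator emulates the inputs of the probe-design cascade: a pair of
annotated genomes (a focal genome and an ortholog genome at controlled
divergence) containing planted single-copy loci, once-duplicated paralog
pairs straddling the 6% design threshold, decoy multigene families, and a
battery of decoy loci each violating exactly one cascade criterion.  It
also simulates recovered-length tables and alignment batches with
machine-readable truth so the statistics modules can be checked
exhaustively.

Model choices
-------------
Substitutions are site-independent and uniform over the three alternative
bases (Jukes-Cantor-like); there are no indels, so planted copies stay
positionally comparable and realized divergence is exact.  Divergence is
applied as an exact substitution count round(p * L) at distinct interior
positions: the first/last 12 bp of every exon stay untouched and the
three intron/flank bases adjacent to each exon boundary are forced to
mismatch the query continuation.  These guards pin local alignments to
exact exon bounds, which keeps the planted truth sharp; real data are
noisier at exon edges (see docs/methods.md).

Paralog pairs meant to survive the cascade are planted at 6.2-7.0%
divergence with a reduced ortholog divergence (2% instead of the 3.65%
genome-wide average) -- retained WGD duplicates are typically
dosage-constrained and evolve more slowly, and the cascade's own
thresholds (>=6% between paralogs, >=90% query identity in the second
genome) leave pairs only a narrow survivable window otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .probedesign import DesignConfig
from .seqio import AnnotationFeature, SequenceRecord, write_fasta

__all__ = [
    "SimConfig",
    "TruthEntry",
    "TruthTable",
    "SimulatedDesign",
    "simulate_annotated_genome",
    "evolve_ortholog_genome",
    "simulate_recovery_table",
    "simulate_alignment_batch",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic design input.

    ``ortholog_divergence`` defaults to the 3.65% genome-wide average
    between the focal genus and its sister; paralog pairs straddle the 6%
    design threshold: qualifying pairs inside ``paralog_divergence_range``,
    a low-divergence decoy below it.
    """

    seed: int = 0
    n_single_copy: int = 14
    n_paralog_pairs: int = 6
    paralog_divergence_range: tuple[float, float] = (0.062, 0.070)
    ortholog_divergence: float = 0.0365
    pair_ortholog_divergence: float = 0.02
    exons_per_locus_range: tuple[int, int] = (2, 3)
    exon_len_range: tuple[int, int] = (160, 300)
    intron_len_range: tuple[int, int] = (150, 650)
    intergenic_len_range: tuple[int, int] = (250, 450)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    decoy_multigene_copy_number: int = 7
    with_decoys: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.paralog_divergence_range
        for d in (lo, hi, self.ortholog_divergence, self.pair_ortholog_divergence):
            if not 0 <= d < 0.75:
                raise ValueError("divergences must lie in [0, 0.75)")
        if lo > hi:
            raise ValueError("paralog_divergence_range is degenerate")
        if self.exon_len_range[0] < 40 or self.intron_len_range[0] < 10:
            raise ValueError("exon/intron length ranges too small")
        if self.intron_len_range[1] > 20 * self.intergenic_len_range[1] + 10_000:
            raise ValueError("intron range exceeds the spacer budget")


# ------------------------------------------------------------ primitives

_EXON_END_PROTECT = 12   # untouched bases at each exon end
_GUARD = 3               # forced-mismatch bases flanking each exon


def _random_seq(rng: np.random.Generator, n: int, comp) -> str:
    return "".join(rng.choice(_BASES, size=n, p=list(comp)))


def _mutate_exact(seq: str, p: float, rng: np.random.Generator,
                  protect_ends: int = 0) -> tuple[str, int]:
    """Substitute exactly round(p*len) interior positions; returns
    (mutated sequence, substitution count)."""
    L = len(seq)
    n_sub = int(round(p * L))
    if n_sub == 0:
        return seq, 0
    eligible = np.arange(protect_ends, L - protect_ends)
    if n_sub > eligible.size:
        raise ValueError("divergence too high for sequence length")
    pos = rng.choice(eligible, size=n_sub, replace=False)
    arr = np.array(list(seq))
    for i in pos:
        alts = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alts[rng.integers(3)]
    return "".join(arr), n_sub


def _force_mismatch(seq_arr: list[str], idx: int, avoid: str) -> None:
    if seq_arr[idx] == avoid:
        order = "ACGT"
        seq_arr[idx] = order[(order.index(avoid) + 1) % 4]


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


# ------------------------------------------------------------ data model


@dataclass
class _Copy:
    """One genomic copy of a planted locus family."""

    scaffold_id: str
    exons: list[str]            # exon sequences, genome order
    introns: list[str]
    flank5: str
    flank3: str
    exon_coords: list[tuple[int, int]] = field(default_factory=list)

    def assemble(self, query_exons: Sequence[str], after_query: str = "") -> str:
        """Build the scaffold and force boundary guards to mismatch the
        query continuation (query = exon concatenation + optional padding)."""
        parts: list[str] = []
        coords: list[tuple[int, int]] = []
        pos = len(self.flank5)
        parts.append(self.flank5)
        for k, ex in enumerate(self.exons):
            coords.append((pos + 1, pos + len(ex)))  # 1-based inclusive
            parts.append(ex)
            pos += len(ex)
            if k < len(self.introns):
                parts.append(self.introns[k])
                pos += len(self.introns[k])
        parts.append(self.flank3)
        seq = list("".join(parts))
        # guards: intron/flank bases adjacent to exon bounds must mismatch
        # the query bases that a boundary-crossing extension would consume
        qcat = "".join(query_exons) + after_query
        qoff = 0
        for k, (lo, hi) in enumerate(coords):
            qoff += len(self.exons[k])
            # right of exon k: subject positions hi..hi+2 vs query qoff..qoff+2
            for g in range(_GUARD):
                si, qi = hi + g, qoff + g
                if si < len(seq) and qi < len(qcat):
                    _force_mismatch(seq, si, qcat[qi])
            # left of exon k+1: subject positions lo2-3..lo2-1 vs query bases
            if k + 1 < len(coords):
                lo2 = coords[k + 1][0]
                for g in range(1, _GUARD + 1):
                    si, qi = lo2 - 1 - g, qoff - g
                    if si >= 0 and qi >= 0:
                        _force_mismatch(seq, si, qcat[qi])
        self.exon_coords = coords
        return "".join(seq)


@dataclass
class _Family:
    query_id: str
    kind: str                    # "single", "pair", "decoy_*"
    copies: list[_Copy]
    query_padding: str = ""
    b_divergence: float = 0.0365
    designed_violation: str = "" # empty for qualifying families

    @property
    def query_seq(self) -> str:
        return "".join(self.copies[0].exons) + self.query_padding


@dataclass
class TruthEntry:
    query_id: str
    kind: str
    copy_number: int
    coords: dict
    realized_paralog_divergence: float | None
    realized_ortholog_divergence: float
    expected_verdict: str          # "retained" | "dropped"
    designed_violation: str
    derived_stage: str             # stage at which the mechanical evaluation drops it


@dataclass
class TruthTable:
    entries: list[TruthEntry]

    def retained_query_ids(self) -> set[str]:
        return {e.query_id for e in self.entries if e.expected_verdict == "retained"}

    def to_json(self) -> str:
        return json.dumps([asdict(e) for e in self.entries], indent=2)


@dataclass
class SimulatedDesign:
    """A complete synthetic design input: genome pair, queries, truth."""

    genome_a: list[SequenceRecord]
    gff_a: list[AnnotationFeature]
    genome_b: list[SequenceRecord]
    gff_b: list[AnnotationFeature]
    queries: list[SequenceRecord]
    truth: TruthTable


# ------------------------------------------------------------ generators


def _make_copy(rng, cfg: SimConfig, scaffold_id: str, exon_lens: Sequence[int],
               intron_lens: Sequence[int] | None = None) -> _Copy:
    if intron_lens is None:
        intron_lens = [int(rng.integers(*cfg.intron_len_range)) for _ in exon_lens[:-1]]
    return _Copy(
        scaffold_id=scaffold_id,
        exons=[_random_seq(rng, L, cfg.base_composition) for L in exon_lens],
        introns=[_random_seq(rng, L, cfg.base_composition) for L in intron_lens],
        flank5=_random_seq(rng, int(rng.integers(*cfg.intergenic_len_range)),
                           cfg.base_composition),
        flank3=_random_seq(rng, int(rng.integers(*cfg.intergenic_len_range)),
                           cfg.base_composition),
    )


def _derive_copy(rng, cfg: SimConfig, src: _Copy, scaffold_id: str,
                 divergence: float) -> _Copy:
    exons = []
    for ex in src.exons:
        mut, _ = _mutate_exact(ex, divergence, rng, protect_ends=_EXON_END_PROTECT)
        exons.append(mut)
    introns = [_mutate_exact(i, divergence, rng)[0] for i in src.introns]
    return _Copy(
        scaffold_id=scaffold_id,
        exons=exons,
        introns=introns,
        flank5=_random_seq(rng, len(src.flank5), cfg.base_composition),
        flank3=_random_seq(rng, len(src.flank3), cfg.base_composition),
    )


def _rand_exon_lens(rng, cfg: SimConfig) -> list[int]:
    n = int(rng.integers(cfg.exons_per_locus_range[0],
                         cfg.exons_per_locus_range[1] + 1))
    return [int(rng.integers(*cfg.exon_len_range)) for _ in range(n)]


def _build_families(cfg: SimConfig, rng) -> list[_Family]:
    fams: list[_Family] = []

    for i in range(cfg.n_single_copy):
        qid = f"q_single_{i:03d}"
        c = _make_copy(rng, cfg, f"{qid}_s1", _rand_exon_lens(rng, cfg))
        fams.append(_Family(qid, "single", [c], b_divergence=cfg.ortholog_divergence))

    for i in range(cfg.n_paralog_pairs):
        qid = f"q_pair_{i:03d}"
        d = float(rng.uniform(*cfg.paralog_divergence_range))
        c1 = _make_copy(rng, cfg, f"{qid}_s1", _rand_exon_lens(rng, cfg))
        c2 = _derive_copy(rng, cfg, c1, f"{qid}_s2", d)
        fams.append(_Family(qid, "pair", [c1, c2],
                            b_divergence=cfg.pair_ortholog_divergence))

    if not cfg.with_decoys:
        return fams

    dv = cfg.ortholog_divergence

    def fam(qid, kind, copies, violation, padding="", b_div=dv):
        fams.append(_Family(qid, kind, copies, query_padding=padding,
                            b_divergence=b_div, designed_violation=violation))

    # each decoy violates exactly one design criterion
    fam("q_decoy_hitlen", "decoy", [_make_copy(rng, cfg, "d_hitlen_s1", [55, 55, 55])],
        "min_hit_len")
    c = _make_copy(rng, cfg, "d_qfrac_s1", [250])
    fam("q_decoy_qfrac", "decoy", [c], "min_hit_query_frac",
        padding=_random_seq(rng, 3000, cfg.base_composition))
    src = _make_copy(rng, cfg, "d_ident_s1", [250, 250, 250])
    mut = _derive_copy(rng, cfg, src, "d_ident_s1", 0.32)
    mut_fam = _Family("q_decoy_identity", "decoy", [mut],
                      b_divergence=dv, designed_violation="min_hit_identity")
    mut_fam.query_override = "".join(src.exons)  # type: ignore[attr-defined]
    fams.append(mut_fam)
    fam("q_decoy_gap", "decoy",
        [_make_copy(rng, cfg, "d_gap_s1", [300, 300], intron_lens=[10_100])],
        "max_cluster_gap")
    c1 = _make_copy(rng, cfg, "d_many_s1", _rand_exon_lens(rng, cfg))
    many = [c1] + [_derive_copy(rng, cfg, c1, f"d_many_s{k}", 0.04)
                   for k in range(2, cfg.decoy_multigene_copy_number + 1)]
    fam("q_decoy_manyloci", "decoy_multigene", many, "max_loci_per_query_initial")
    fam("q_decoy_coverage", "decoy",
        [_make_copy(rng, cfg, "d_cov_s1", [300, 300, 300])], "min_sum_coverage",
        padding=_random_seq(rng, 350, cfg.base_composition))
    fam("q_decoy_shorthit", "decoy",
        [_make_copy(rng, cfg, "d_short_s1", [80, 300, 300])], "min_single_hit_len")
    fam("q_decoy_intron", "decoy",
        [_make_copy(rng, cfg, "d_intr_s1", [400, 400], intron_lens=[1400])],
        "max_intron_len")
    c1 = _make_copy(rng, cfg, "d_three_s1", _rand_exon_lens(rng, cfg))
    fam("q_decoy_threeloci", "decoy_multigene",
        [c1, _derive_copy(rng, cfg, c1, "d_three_s2", 0.044),
         _derive_copy(rng, cfg, c1, "d_three_s3", 0.044)], "max_loci_per_query")
    c1 = _make_copy(rng, cfg, "d_lowdiv_s1", _rand_exon_lens(rng, cfg))
    fam("q_decoy_lowdiv", "decoy",
        [c1, _derive_copy(rng, cfg, c1, "d_lowdiv_s2", 0.03)],
        "min_interlocus_divergence", b_div=cfg.pair_ortholog_divergence)
    fam("q_decoy_orthodiv", "decoy",
        [_make_copy(rng, cfg, "d_ortho_s1", _rand_exon_lens(rng, cfg))],
        "max_ortholog_divergence", b_div=0.25)
    fam("q_decoy_shortexon", "decoy",
        [_make_copy(rng, cfg, "d_shex_s1", [79, 79, 79])], "min_exon_len")
    src = _make_copy(rng, cfg, "d_sumid_s1", [250, 250, 250])
    mut = _derive_copy(rng, cfg, src, "d_sumid_s1", 0.13)
    mut_fam = _Family("q_decoy_sumidentity", "decoy", [mut],
                      b_divergence=dv, designed_violation="min_sum_identity")
    mut_fam.query_override = "".join(src.exons)  # type: ignore[attr-defined]
    fams.append(mut_fam)
    return fams


def _family_query(fam: _Family) -> str:
    override = getattr(fam, "query_override", None)
    if override is not None:
        return override + fam.query_padding
    return fam.query_seq


def _annotate(fams: Sequence[_Family], genome_label: str,
              copies_attr: str) -> list[AnnotationFeature]:
    feats: list[AnnotationFeature] = []
    for fam in fams:
        for c in getattr(fam, copies_attr):
            gid = f"{c.scaffold_id}.gene"
            tid = f"{c.scaffold_id}.mRNA1"
            lo = c.exon_coords[0][0]
            hi = c.exon_coords[-1][1]
            feats.append(AnnotationFeature(c.scaffold_id, "gene", lo, hi, "+",
                                           gid, None, "protein_coding"))
            feats.append(AnnotationFeature(c.scaffold_id, "mRNA", lo, hi, "+",
                                           tid, gid, "protein_coding"))
            for n, (elo, ehi) in enumerate(c.exon_coords, 1):
                feats.append(AnnotationFeature(c.scaffold_id, "exon", elo, ehi, "+",
                                               f"{tid}.exon{n}", tid))
    return feats


def _decor_features(rng, cfg, records: list[SequenceRecord]) -> list[AnnotationFeature]:
    """Non-target annotation (rRNA, pseudogene, organellar scaffold) so the
    biotype policy has something to act on."""
    feats = []
    for sid, ftype, ttype, biotype in (
        ("decor_rrna", "gene", "rRNA", "rRNA"),
        ("decor_pseudo", "pseudogene", "pseudogenic_transcript", "pseudogene"),
        ("decor_lnc", "gene", "lnc_RNA", "lnc_rna"),
        ("plastid_decor", "gene", "mRNA", "protein_coding"),
    ):
        seq = _random_seq(rng, 600, cfg.base_composition)
        records.append(SequenceRecord(sid, seq))
        feats.append(AnnotationFeature(sid, ftype, 50, 550, "+", f"{sid}.g", None, biotype))
        feats.append(AnnotationFeature(sid, ttype, 50, 550, "+", f"{sid}.t", f"{sid}.g", biotype))
        feats.append(AnnotationFeature(sid, "exon", 50, 550, "+", f"{sid}.e1", f"{sid}.t"))
    return feats


# ------------------------------------------------- mechanical truth


def _evaluate_family(fam: _Family, copies_a: list[tuple[_Copy, str]],
                     copies_b: list[tuple[_Copy, str]],
                     cfg: DesignConfig) -> tuple[str, str]:
    """Predict the cascade verdict from planted structure alone
    (position-wise statistics; no alignment).  Returns (verdict, stage)."""
    q_exons = (getattr(fam, "query_override", None) or
               "".join(fam.copies[0].exons)).upper()
    q_exon_lens = [len(e) for e in fam.copies[0].exons]
    qlen = len(q_exons) + len(fam.query_padding)

    def genome_clusters(copies: list[tuple[_Copy, str]]):
        clusters = []
        for copy, _seq in copies:
            # per-exon identity: position-wise against the query exons
            off = 0
            hits = []
            for k, L in enumerate(q_exon_lens):
                q_ex = q_exons[off:off + L]
                s_ex = copy.exons[k]
                mm = _mismatches(q_ex, s_ex)
                ident = 100.0 * (L - mm) / L
                lo, hi = copy.exon_coords[k]
                hits.append({"len": L, "ident": ident, "lo": lo, "hi": hi, "k": k})
                off += L
            kept = [h for h in hits
                    if h["len"] > cfg.min_hit_len
                    and h["len"] > cfg.min_hit_query_frac * qlen
                    and h["ident"] >= cfg.min_hit_identity]
            if not kept:
                continue
            # split on genomic gaps exceeding the cluster limit
            cur = [kept[0]]
            for h in kept[1:]:
                if h["lo"] - cur[-1]["hi"] - 1 > cfg.max_cluster_gap:
                    clusters.append({"copy": copy, "hits": cur})
                    cur = [h]
                else:
                    cur.append(h)
            clusters.append({"copy": copy, "hits": cur})
        return clusters

    def run(copies):
        clusters = genome_clusters(copies)
        if not clusters:
            return None, "initial_hit_filter"
        if len(clusters) > cfg.max_loci_per_query_initial:
            return None, "initial_count_filter"
        surviving = []
        for cl in clusters:
            hits = cl["hits"]
            cov = 100.0 * sum(h["len"] for h in hits) / qlen
            wid = (sum(h["ident"] * h["len"] for h in hits)
                   / sum(h["len"] for h in hits))
            gaps_ok = all(b["lo"] - a["hi"] - 1 <= cfg.max_intron_len
                          for a, b in zip(hits, hits[1:]))
            if (cov >= cfg.min_sum_coverage and wid >= cfg.min_sum_identity
                    and all(h["len"] >= cfg.min_single_hit_len for h in hits)
                    and gaps_ok):
                surviving.append(cl)
        if not surviving:
            return None, "refined_locus_filter"
        if len(surviving) > cfg.max_loci_per_query:
            return None, "refined_count_filter"
        if len(surviving) == 2:
            a, b = surviving
            ca = "".join(a["copy"].exons[h["k"]] for h in a["hits"])
            cb = "".join(b["copy"].exons[h["k"]] for h in b["hits"])
            if len(ca) == len(cb):
                div = 100.0 * _mismatches(ca, cb) / len(ca)
                if div < cfg.min_interlocus_divergence:
                    return None, "interlocus_divergence"
        return surviving, "passed"

    surv_a, stage_a = run(copies_a)
    if surv_a is None:
        return "dropped", stage_a
    surv_b, stage_b = run(copies_b)
    if surv_b is None:
        return "dropped", f"genome_b:{stage_b}"
    if len(surv_a) != len(surv_b):
        return "dropped", "cross_genome:unequal_locus_counts"
    for ca, cb in zip(surv_a, surv_b):
        ea = "".join(ca["copy"].exons[h["k"]] for h in ca["hits"])
        eb = "".join(cb["copy"].exons[h["k"]] for h in cb["hits"])
        div = 100.0 * _mismatches(ea, eb) / len(ea)
        if div > cfg.max_ortholog_divergence:
            return "dropped", "cross_genome:max_ortholog_divergence"
        if all(h["len"] < cfg.min_exon_len for h in ca["hits"]):
            return "dropped", "cross_genome:min_exon_len"
    return "retained", "final"


def simulate_annotated_genome(
    cfg: SimConfig | None = None, design_cfg: DesignConfig | None = None
) -> SimulatedDesign:
    """Generate the full synthetic design input (genome pair + queries +
    truth), reproducible from ``cfg.seed``."""
    cfg = cfg or SimConfig()
    design_cfg = design_cfg or DesignConfig()
    rng = np.random.default_rng(cfg.seed)
    fams = _build_families(cfg, rng)

    genome_a: list[SequenceRecord] = []
    genome_b: list[SequenceRecord] = []
    queries: list[SequenceRecord] = []
    entries: list[TruthEntry] = []

    for fam in fams:
        query = _family_query(fam)
        q_exons = getattr(fam, "query_override", None) or "".join(fam.copies[0].exons)
        queries.append(SequenceRecord(fam.query_id, query))
        # query exon segments, used to place boundary mismatch guards
        lens = [len(e) for e in fam.copies[0].exons]
        offs = np.concatenate([[0], np.cumsum(lens)])
        q_segs = [q_exons[offs[k]:offs[k + 1]] for k in range(len(lens))]
        copies_a: list[tuple[_Copy, str]] = []
        copies_b: list[tuple[_Copy, str]] = []
        b_copies_store: list[_Copy] = []
        for copy in fam.copies:
            seq_a = copy.assemble(q_segs, after_query=fam.query_padding)
            genome_a.append(SequenceRecord(copy.scaffold_id, seq_a))
            copies_a.append((copy, seq_a))
            bcopy = _derive_copy(rng, cfg, copy, copy.scaffold_id, fam.b_divergence)
            seq_b = bcopy.assemble(q_segs, after_query=fam.query_padding)
            genome_b.append(SequenceRecord(copy.scaffold_id, seq_b))
            copies_b.append((bcopy, seq_b))
            b_copies_store.append(bcopy)
        fam.b_copies = b_copies_store  # type: ignore[attr-defined]

        verdict, stage = _evaluate_family(fam, copies_a, copies_b, design_cfg)
        d_par = None
        if len(fam.copies) == 2:
            ca = "".join(fam.copies[0].exons)
            cb = "".join(fam.copies[1].exons)
            d_par = 100.0 * _mismatches(ca, cb) / len(ca)
        ea = "".join(fam.copies[0].exons)
        eb = "".join(copies_b[0][0].exons)
        d_orth = 100.0 * _mismatches(ea, eb) / len(ea)
        entries.append(TruthEntry(
            query_id=fam.query_id,
            kind=fam.kind,
            copy_number=len(fam.copies),
            coords={c.scaffold_id: c.exon_coords for c in fam.copies},
            realized_paralog_divergence=d_par,
            realized_ortholog_divergence=d_orth,
            expected_verdict=verdict,
            designed_violation=fam.designed_violation,
            derived_stage=stage,
        ))

    gff_a = _annotate(fams, "A", "copies")
    gff_b = _annotate(fams, "B", "b_copies")
    decor = _decor_features(rng, cfg, genome_a)
    gff_a.extend(decor)
    # mirror the decor scaffolds into genome B unchanged
    decor_ids = {f.seq_id for f in decor}
    for rec in genome_a:
        if rec.id in decor_ids and all(r.id != rec.id for r in genome_b):
            genome_b.append(SequenceRecord(rec.id, rec.seq))
    gff_b.extend(decor)

    return SimulatedDesign(genome_a, gff_a, genome_b, gff_b, queries,
                           TruthTable(entries))


def evolve_ortholog_genome(
    genome: Sequence[SequenceRecord],
    gff: Sequence[AnnotationFeature],
    divergence: float,
    seed: int,
) -> tuple[list[SequenceRecord], list[AnnotationFeature]]:
    """Apply per-site substitutions at the given rate to every sequence;
    annotation coordinates are preserved (indel-free model)."""
    if not 0 <= divergence < 0.75:
        raise ValueError("divergence must lie in [0, 0.75)")
    rng = np.random.default_rng(seed)
    out = []
    for rec in genome:
        arr = np.array(list(rec.seq))
        hit = rng.random(arr.size) < divergence
        for i in np.flatnonzero(hit):
            alts = [b for b in "ACGT" if b != arr[i]]
            arr[i] = alts[rng.integers(3)]
        out.append(SequenceRecord(rec.id, "".join(arr), rec.description))
    return out, list(gff)


# ------------------------------------------------------------ tables


def simulate_recovery_table(
    n_samples: int,
    reference: Sequence,
    dropout_rate: float,
    length_beta_params: tuple[float, float] = (6.0, 2.0),
    seed: int = 0,
):
    """Simulate a seq_lengths-style recovery table.

    ``reference`` is either target lengths (ints) or SequenceRecords.
    Returns (RecoveryMatrix, truth grid dict computed by brute force).
    """
    from .recovery import RecoveryMatrix, LENGTH_THRESHOLDS, PRESENCE_THRESHOLDS

    rng = np.random.default_rng(seed)
    lengths = [len(r.seq) if hasattr(r, "seq") else int(r) for r in reference]
    loci = [r.id if hasattr(r, "id") else f"locus{i+1:03d}"
            for i, r in enumerate(reference)]
    a, b = length_beta_params
    rec = np.zeros((n_samples, len(lengths)))
    for i in range(n_samples):
        for j, L in enumerate(lengths):
            if rng.random() < dropout_rate:
                continue
            rec[i, j] = round(L * rng.beta(a, b))
    matrix = RecoveryMatrix(
        samples=[f"sample{i+1:02d}" for i in range(n_samples)],
        loci=loci,
        recovered_len=rec,
        target_len=np.array(lengths, dtype=float),
    )
    # brute-force truth grid (independent double loop)
    truth: dict = {"rows": {}, "n_zero": 0}
    nz = 0
    for j in range(len(lengths)):
        if all(rec[i, j] == 0 for i in range(n_samples)):
            nz += 1
    truth["n_zero"] = nz
    for L in LENGTH_THRESHOLDS:
        for P in PRESENCE_THRESHOLDS:
            n = 0
            for j, tlen in enumerate(lengths):
                good = 0
                for i in range(n_samples):
                    frac = min(rec[i, j] / tlen, 1.0)
                    if frac >= L:
                        good += 1
                if good / n_samples >= P:
                    n += 1
            truth["rows"][(L, P)] = n
    return matrix, truth


def write_seq_lengths(matrix, path: str | Path) -> None:
    """Write a RecoveryMatrix in the seq_lengths TSV dialect."""
    with open(path, "w") as fh:
        fh.write("Species\t" + "\t".join(matrix.loci) + "\n")
        fh.write("MeanLength\t" + "\t".join(f"{t:g}" for t in matrix.target_len) + "\n")
        for i, s in enumerate(matrix.samples):
            fh.write(s + "\t" + "\t".join(f"{v:g}" for v in matrix.recovered_len[i])
                     + "\n")


def simulate_alignment_batch(
    n_aln: int,
    taxa: int,
    length: int,
    missing_rate: float,
    pi_fraction: float,
    seed: int = 0,
    singleton_fraction: float = 0.2,
):
    """Simulate alignments with planted column classes plus missing data.

    Returns (alignments, truth) where truth holds, per alignment, the
    post-injection exhaustive column classification (computed with an
    independent tally, the missing set being {'-', '?', 'N'}).
    """
    from .alnstats import AlignmentMatrix

    rng = np.random.default_rng(seed)
    alignments = []
    truths = []
    miss_syms = np.array(list("-?N"))
    for a in range(n_aln):
        cols = []
        for _ in range(length):
            u = rng.random()
            if u < pi_fraction and taxa >= 4:
                b1, b2 = rng.choice(4, size=2, replace=False)
                n1 = int(rng.integers(2, taxa - 1))
                col = np.array([_BASES[b1]] * n1 + [_BASES[b2]] * (taxa - n1))
                rng.shuffle(col)
            elif u < pi_fraction + singleton_fraction and taxa >= 2:
                b1, b2 = rng.choice(4, size=2, replace=False)
                col = np.array([_BASES[b1]] * taxa)
                col[rng.integers(taxa)] = _BASES[b2]
            else:
                col = np.array([_BASES[rng.integers(4)]] * taxa)
            cols.append(col)
        data = np.stack(cols, axis=1)
        if missing_rate > 0:
            mask = rng.random(data.shape) < missing_rate
            data[mask] = miss_syms[rng.integers(0, 3, size=int(mask.sum()))]
        aln = AlignmentMatrix([f"t{k+1:02d}" for k in range(taxa)], data)
        # independent exhaustive tally
        n_const = n_sing = n_pi = 0
        for j in range(length):
            vals = [c for c in data[:, j] if c not in "-?N"]
            if len(set(vals)) <= 1:
                n_const += 1
                continue
            counts = {}
            for v in vals:
                if v in "ACGT":
                    counts[v] = counts.get(v, 0) + 1
            if sum(1 for x in counts.values() if x >= 2) >= 2:
                n_pi += 1
            else:
                n_sing += 1
        alignments.append(aln)
        truths.append({"constant": n_const, "singleton": n_sing,
                       "parsimony_informative": n_pi})
    return alignments, truths


# ------------------------------------------------------------ writers


def write_gff(features: Sequence[AnnotationFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.id}"]
            if f.parent_id:
                attrs.append(f"Parent={f.parent_id}")
            if f.biotype:
                attrs.append(f"biotype={f.biotype}")
            fh.write(f"{f.seq_id}\tprobeforge_sim\t{f.feature_type}\t{f.start}\t"
                     f"{f.end}\t.\t{f.strand}\t.\t{';'.join(attrs)}\n")


def write_simulated_design(design: SimulatedDesign, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(design.genome_a, outdir / "genome_A.fasta")
    write_fasta(design.genome_b, outdir / "genome_B.fasta")
    write_fasta(design.queries, outdir / "queries.fasta")
    write_gff(design.gff_a, outdir / "genome_A.gff3")
    write_gff(design.gff_b, outdir / "genome_B.gff3")
    with open(outdir / "truth.json", "w") as fh:
        fh.write(design.truth.to_json())
        fh.write("\n")
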