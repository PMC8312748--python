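"""Local similarity search: hit model, tabular I/O, and an exact built-in
aligner.

The engine performs affine-gap Smith-Waterman (Gotoh recurrences) and
then splits each reported alignment path wherever its running score drops
more than ``x_dropoff`` below the running maximum -- the role X-dropoff
plays in seeded aligners.  Alignments therefore never bridge
low-similarity stretches such as introns, and hits over a multi-exon
locus come out exon-wise.  Multiple hits per query/subject pair are
produced by re-running the DP with previously explored subject regions
masked, until the best score drops below the effective threshold.  For
large subjects, candidate regions are located first with an 11-mer
two-seed heuristic and the DP runs only inside padded windows; below
``full_dp_max_subject`` (or with ``word_size=0``) the whole subject is
scanned, which makes the engine exactly comparable to a brute-force DP
oracle.

E-values use the Karlin-Altschul formula with K=0.41 and lambda=0.625.
These constants are approximate for the default scoring (+2/-3, gap
5+2L); score thresholds are the primary cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "Hit",
    "SearchParams",
    "HitTableFormatError",
    "read_hit_table",
    "write_hit_table",
    "local_search",
    "search_pair",
    "percent_divergence",
    "best_local_alignment",
]

KARLIN_K = 0.41
KARLIN_LAMBDA = 0.625
_LN2 = math.log(2.0)

# base encoding: A,C,G,T -> 0..3; N / IUPAC ambiguity -> 4 (never matches);
# masked positions -> 5 (large penalty, uncrossable by capped gaps in practice)
_ENC = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i
_MASK_CODE = 5
_MASK_PENALTY = -(10**6)  # fits int32 with headroom


def encode_seq(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


@dataclass(frozen=True)
class Hit:
    """One local alignment between a query and a subject sequence.

    Coordinates are 1-based inclusive; ``s_start > s_end`` marks a
    minus-strand hit.  Field order follows BLAST tabular outfmt 6.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    score: int = 0  # raw score; not part of outfmt 6

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    @property
    def s_lo(self) -> int:
        return min(self.s_start, self.s_end)

    @property
    def s_hi(self) -> int:
        return max(self.s_start, self.s_end)

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass(frozen=True)
class SearchParams:
    """Engine parameters (BLASTN-like defaults; E-value lowered to 1e-5)."""

    e_value_max: float = 1e-5
    min_raw_score: int = 40
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5       # positive penalties; a gap of length L costs open + extend*L
    gap_extend: int = 2
    x_dropoff: int = 40
    word_size: int = 11         # 0 = exhaustive DP over the whole subject
    full_dp_max_subject: int = 0
    window_pad: int = 300
    max_hits_per_pair: int = 64

    def __post_init__(self) -> None:
        if self.e_value_max <= 0:
            raise ValueError("e_value_max must be > 0")

    def min_score_for(self, m: int, n: int) -> int:
        """Effective raw-score threshold combining min_raw_score and E-value."""
        # E = K m n exp(-lambda S) <= e_value_max  =>  S >= ln(K m n / Emax)/lambda
        s_e = math.log(max(KARLIN_K * m * n, 1e-300) / self.e_value_max) / KARLIN_LAMBDA
        return max(self.min_raw_score, int(math.ceil(s_e)))


class HitTableFormatError(ValueError):
    pass


_OUTFMT6_COLS = 12


def read_hit_table(path: str | Path) -> list[Hit]:
    """Read BLAST tabular outfmt 6 (12 standard columns)."""
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _OUTFMT6_COLS:
                raise HitTableFormatError(
                    f"{path}:{lineno}: expected {_OUTFMT6_COLS} columns, got {len(cols)}"
                )
            try:
                hits.append(
                    Hit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=float(cols[2]),
                        align_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        e_value=float(cols[10]),
                        bit_score=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise HitTableFormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[Hit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t{h.align_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.e_value:.2e}\t{h.bit_score:.1f}\n"
            )


@njit(cache=False)
def _sw_matrix(q, s, match, mismatch, gap_open, gap_ext):  # pragma: no cover - numba
    """Fill the affine-gap Smith-Waterman matrices (Gotoh recurrences).

    H[i][j] = best score of a local alignment ending at (query i, subject j);
    E = best score ending in a gap that consumes the subject, F likewise for
    the query.  A gap of length L costs gap_open + gap_ext * L.  Returns
    (H, E, F, best, bi, bj); best-cell ties resolve to the smallest (i, j).
    """
    m = q.shape[0]
    n = s.shape[0]
    NEG = -(2**30)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    ge = gap_ext
    go = gap_open + gap_ext  # cost of opening a length-1 gap
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qa = q[i - 1]
        Hp = H[i - 1]
        Hr = H[i]
        Er = E[i]
        Fp = F[i - 1]
        Fr = F[i]
        e = NEG
        for j in range(1, n + 1):
            sb = s[j - 1]
            if qa == sb and qa < 4:
                sc = match
            elif qa >= 5 or sb >= 5:
                sc = _MASK_PENALTY
            else:
                sc = mismatch
            e_open = Hr[j - 1] - go
            if e - ge >= e_open:
                e = e - ge
            else:
                e = e_open
            Er[j] = e
            f_open = Hp[j] - go
            f = Fp[j] - ge
            if f_open > f:
                f = f_open
            Fr[j] = f
            h = Hp[j - 1] + sc
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hr[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _traceback_path(H, E, F, q, s, bi, bj, params: SearchParams):
    """Walk back from the best cell through the Gotoh state machine.

    Returns a forward-ordered list of per-column steps
    ``(ds, dq, dj, is_match)`` plus the path origin (i0, j0).  Move
    preference at equal score: diagonal, then gap consuming the subject,
    then gap consuming the query; gaps prefer re-opening (shortest gap).
    """
    match, mismatch = params.match, params.mismatch
    ge = params.gap_extend
    go = params.gap_open + params.gap_extend
    i, j = bi, bj
    steps = []
    state = "H"
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            qa, sb = q[i - 1], s[j - 1]
            if qa == sb and qa < 4:
                sc = match
            elif qa >= 5 or sb >= 5:
                sc = _MASK_PENALTY
            else:
                sc = mismatch
            if H[i - 1][j - 1] + sc == H[i][j]:
                steps.append((sc, 1, 1, sc == match))
                i -= 1
                j -= 1
            elif E[i][j] == H[i][j]:
                state = "E"
            elif F[i][j] == H[i][j]:
                state = "F"
            else:  # pragma: no cover
                raise RuntimeError("traceback failed")
        elif state == "E":
            # gap consuming the subject; prefer re-opening
            if H[i][j - 1] - go == E[i][j]:
                steps.append((-go, 0, 1, False))
                j -= 1
                state = "H"
            else:
                steps.append((-ge, 0, 1, False))
                j -= 1
                # stay in E: E[i][j] was E[i][j-1] - ge
        else:  # state == "F"
            if H[i - 1][j] - go == F[i][j]:
                steps.append((-go, 1, 0, False))
                i -= 1
                state = "H"
            else:
                steps.append((-ge, 1, 0, False))
                i -= 1
    steps.reverse()
    return steps, i, j  # path starts just after (i, j)


def segment_alignment_path(steps, x_dropoff: int):
    """Split an alignment path wherever its running score falls more than
    ``x_dropoff`` below the running maximum (the role X-dropoff plays in
    seeded aligners: extensions across long low-scoring stretches such as
    introns are cut, yielding exon-wise alignments).

    Returns ``(start_idx, end_idx_inclusive, score)`` triples of maximal
    climbing segments; negative-prefix steps are skipped Kadane-style.
    """
    segments = []
    seg_start = 0
    c = 0
    cmax = 0
    tmax = -1
    for t, (ds, _dq, _dj, _m) in enumerate(steps):
        c += ds
        if c > cmax:
            cmax = c
            tmax = t
        if c < 0 or c < cmax - x_dropoff:
            if cmax > 0 and tmax >= seg_start:
                segments.append((seg_start, tmax, cmax))
            seg_start = t + 1
            c = 0
            cmax = 0
            tmax = t
    if cmax > 0 and tmax >= seg_start:
        segments.append((seg_start, tmax, cmax))
    return segments


def _segment_stats(steps, i0, j0, seg):
    """Alignment statistics of one path segment (coordinates 1-based).

    Gap opens count maximal gap runs per side; align_length counts all
    columns including gap columns."""
    start, end, score = seg
    qpos, spos = i0, j0
    for _ds, dq, dj, _m in steps[:start]:
        qpos += dq
        spos += dj
    q_start, s_start = qpos + 1, spos + 1
    matches = mismatches = gap_cols = gap_opens = 0
    prev_gap = 0  # 0 none, 1 subject-consuming, 2 query-consuming
    for _ds, dq, dj, is_match in steps[start : end + 1]:
        if dq == 1 and dj == 1:
            if is_match:
                matches += 1
            else:
                mismatches += 1
            prev_gap = 0
        else:
            kind = 1 if dj == 1 else 2
            if kind != prev_gap:
                gap_opens += 1
            prev_gap = kind
            gap_cols += 1
        qpos += dq
        spos += dj
    return {
        "q_start": q_start,
        "q_end": qpos,
        "s_start": s_start,
        "s_end": spos,
        "matches": matches,
        "mismatches": mismatches,
        "gap_opens": gap_opens,
        "align_length": matches + mismatches + gap_cols,
        "score": score,
    }


def bit_score(raw: float) -> float:
    return (KARLIN_LAMBDA * raw - math.log(KARLIN_K)) / _LN2


def e_value(raw: float, m: int, n: int) -> float:
    return KARLIN_K * m * n * math.exp(-KARLIN_LAMBDA * raw)


def _iterative_hits(qcode, scode, params: SearchParams, m_full: int, n_full: int):
    """Repeated SW with masking of reported subject regions (one window).

    Each round takes the best remaining local alignment, splits its path at
    X-dropoff points, reports the above-threshold segments, and masks the
    whole explored subject span before the next round."""
    out = []
    sc = scode.copy()
    thr = params.min_score_for(m_full, n_full)
    for _ in range(params.max_hits_per_pair):
        H, E, F, best, bi, bj = _sw_matrix(
            qcode, sc, params.match, params.mismatch,
            params.gap_open, params.gap_extend,
        )
        if best < thr:
            break
        steps, i0, j0 = _traceback_path(H, E, F, qcode, sc, bi, bj, params)
        for seg in segment_alignment_path(steps, params.x_dropoff):
            tb = _segment_stats(steps, i0, j0, seg)
            if tb["score"] >= thr:
                out.append((tb, tb["score"]))
        sc[j0:bj] = _MASK_CODE  # mask the full explored span
    return out


def _query_kmers(qcode: np.ndarray, word_size: int):
    """(kmer, qpos) pairs over all unambiguous words of the query."""
    m = qcode.shape[0]
    out = []
    if m < word_size:
        return out
    mask = (1 << (2 * word_size)) - 1
    kmer = 0
    run = 0
    for qpos in range(m):
        b = int(qcode[qpos])
        if b >= 4:
            run = 0
            kmer = 0
            continue
        kmer = ((kmer << 2) | b) & mask
        run += 1
        if run >= word_size:
            out.append((kmer, qpos - word_size + 1))
    return out


def build_kmer_index(scode: np.ndarray, word_size: int, index=None, tag=0) -> dict:
    """Position index of all unambiguous k-mers of a subject sequence.

    Entries are (tag, position) pairs so several subjects can share one
    index."""
    n = scode.shape[0]
    if index is None:
        index = {}
    if n < word_size:
        return index
    mask = (1 << (2 * word_size)) - 1
    kmer = 0
    run = 0
    for pos in range(n):
        b = int(scode[pos])
        if b >= 4:
            run = 0
            kmer = 0
            continue
        kmer = ((kmer << 2) | b) & mask
        run += 1
        if run >= word_size:
            index.setdefault(kmer, []).append((tag, pos - word_size + 1))
    return index


def _seed_windows(seeds, n: int, params: SearchParams):
    """Merge seeds into candidate subject windows.

    ``seeds`` are (diag, spos, qpos) triples for one (query, subject,
    orientation).  Seeds are grouped into diagonal bands (two-seed rule: a
    band must contain at least two seeds); each band yields a window of
    padded seed extent; overlapping windows merge.  Returns 0-based
    half-open (lo, hi) windows."""
    if len(seeds) < 2:
        return []
    seeds = sorted(seeds)
    band = 2 * params.x_dropoff  # generous diagonal drift allowance
    windows = []
    i = 0
    while i < len(seeds):
        j = i
        while j + 1 < len(seeds) and seeds[j + 1][0] - seeds[i][0] <= band:
            j += 1
        group = seeds[i : j + 1]
        if len(group) >= 2:
            s_min = min(g[1] for g in group)
            s_max = max(g[1] for g in group) + params.word_size
            pad = params.window_pad
            windows.append((max(0, s_min - pad), min(n, s_max + pad)))
        i = j + 1
    if not windows:
        return []
    windows.sort()
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _drop_contained(hits: list[Hit]) -> list[Hit]:
    """Drop hits wholly contained (query and subject side) in a better hit
    of the same query/subject pair and strand."""
    keep = []
    for h in hits:
        contained = False
        for o in hits:
            if (o is h or o.query_id != h.query_id or o.subject_id != h.subject_id
                    or o.strand != h.strand):
                continue
            if (
                o.score >= h.score
                and o.q_start <= h.q_start
                and o.q_end >= h.q_end
                and o.s_lo <= h.s_lo
                and o.s_hi >= h.s_hi
                and (o.score > h.score or o.q_span > h.q_span or
                     (o.q_span == h.q_span and (o.s_hi - o.s_lo) > (h.s_hi - h.s_lo)))
            ):
                contained = True
                break
        if not contained:
            keep.append(h)
    return keep


def _hits_for_windows(query, subject, qcode, scode, windows, strand, n,
                      params: SearchParams) -> list[Hit]:
    m = len(query.seq)
    hits: list[Hit] = []
    for lo, hi in windows:
        for tb, raw in _iterative_hits(qcode, scode[lo:hi], params, m, n):
            s1 = lo + tb["s_start"]
            s2 = lo + tb["s_end"]
            if strand == "-":
                s1, s2 = n - s1 + 1, n - s2 + 1
            ev = e_value(raw, m, n)
            if ev > params.e_value_max:
                continue
            hits.append(
                Hit(
                    query_id=query.id,
                    subject_id=subject.id,
                    percent_identity=100.0 * tb["matches"] / tb["align_length"],
                    align_length=tb["align_length"],
                    mismatches=tb["mismatches"],
                    gap_opens=tb["gap_opens"],
                    q_start=tb["q_start"],
                    q_end=tb["q_end"],
                    s_start=s1,
                    s_end=s2,
                    e_value=ev,
                    bit_score=bit_score(raw),
                    score=raw,
                )
            )
    return hits


def search_pair(
    query: SequenceRecord,
    subject: SequenceRecord,
    params: SearchParams | None = None,
) -> list[Hit]:
    """All above-threshold local alignments of one query against one
    subject (both strands)."""
    params = params or SearchParams()
    return local_search([query], [subject], params)


def local_search(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    params: SearchParams | None = None,
) -> list[Hit]:
    """Search every query against every subject; deterministic output order
    (query_id, descending bit score, subject_id, subject coordinate).

    With ``word_size > 0`` candidate regions come from an 11-mer two-seed
    scan of a shared subject index and the DP runs only inside padded
    windows; subjects no longer than ``full_dp_max_subject`` (or
    ``word_size=0``) are scanned exhaustively, which makes the engine
    directly comparable to a brute-force DP oracle.
    """
    params = params or SearchParams()
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")

    scodes = {}
    seeded: list[int] = []
    exhaustive: list[int] = []
    for idx, sub in enumerate(subjects):
        plus = encode_seq(sub.seq)
        minus = encode_seq(reverse_complement(sub.seq))
        scodes[idx] = {"+": plus, "-": minus}
        if params.word_size > 0 and len(sub.seq) > params.full_dp_max_subject:
            seeded.append(idx)
        else:
            exhaustive.append(idx)

    index: dict = {}
    if seeded:
        # one shared index over both orientations of all large subjects;
        # tags are (subject_idx, strand_code)
        for idx in seeded:
            build_kmer_index(scodes[idx]["+"], params.word_size, index, tag=2 * idx)
            build_kmer_index(scodes[idx]["-"], params.word_size, index, tag=2 * idx + 1)

    all_hits: list[Hit] = []
    for query in queries:
        qcode = encode_seq(query.seq)
        if np.all(qcode >= 4):
            warnings.warn(f"query {query.id!r} contains no unambiguous bases; no hits")
            continue
        # exhaustive subjects: full DP over both strands
        for idx in exhaustive:
            sub = subjects[idx]
            n = len(sub.seq)
            for strand in "+-":
                all_hits.extend(_hits_for_windows(
                    query, sub, qcode, scodes[idx][strand], [(0, n)], strand, n,
                    params))
        # seeded subjects: collect seeds per (subject, strand), then windows
        if seeded:
            per_tag: dict[int, list] = {}
            for kmer, qpos in _query_kmers(qcode, params.word_size):
                entries = index.get(kmer)
                if entries:
                    for tag, spos in entries:
                        per_tag.setdefault(tag, []).append((spos - qpos, spos, qpos))
            for tag in sorted(per_tag):
                idx, strand = tag // 2, "+-"[tag % 2]
                sub = subjects[idx]
                n = len(sub.seq)
                windows = _seed_windows(per_tag[tag], n, params)
                if windows:
                    all_hits.extend(_hits_for_windows(
                        query, sub, qcode, scodes[idx][strand], windows, strand,
                        n, params))
    all_hits = _drop_contained(all_hits)
    all_hits.sort(key=lambda h: (h.query_id, -h.bit_score, h.subject_id, h.s_lo, h.q_start))
    return all_hits


def best_local_alignment(
    a: str, b: str, params: SearchParams | None = None
) -> dict | None:
    """Best-scoring local alignment of two sequences (plus strand only);
    returns traceback stats plus raw score, or None if nothing scores > 0."""
    params = params or SearchParams()
    qc, sc = encode_seq(a), encode_seq(b)
    H, E, F, best, bi, bj = _sw_matrix(
        qc, sc, params.match, params.mismatch,
        params.gap_open, params.gap_extend,
    )
    if best <= 0:
        return None
    steps, i0, j0 = _traceback_path(H, E, F, qc, sc, bi, bj, params)
    return _segment_stats(steps, i0, j0, (0, len(steps) - 1, int(best)))


def percent_divergence(
    a: str, b: str, params: SearchParams | None = None, min_score: int = 20
) -> tuple[float, bool]:
    """Divergence of two sequences: 100 - identity of their best local
    alignment.  Returns ``(divergence, aligned)``; if no alignment reaches
    ``min_score`` the divergence is 100.0 with ``aligned=False``."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    tb = best_local_alignment(a, b, params)
    if tb is None or tb["score"] < min_score:
        return 100.0, False
    return 100.0 - 100.0 * tb["matches"] / tb["align_length"], True
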