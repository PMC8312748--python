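"""Independent brute-force oracles used by the test suite.

These deliberately use the simplest possible formulations (explicit
loops over plain Python lists, no vectorization) so they can be trusted
by inspection.  They share only the *semantics* contract with the
production code: affine-gap local alignment (gap of length L costs
open + extend*L) with the documented tie-breaks, X-dropoff path
segmentation, masking of explored subject regions, and the same
score/E-value thresholds.
"""

from __future__ import annotations

import math

MASK = "!"  # oracle-side mask symbol
NEG = -(10**9)


def _score(a: str, b: str, match: int, mismatch: int) -> int:
    if a == MASK or b == MASK:
        return -(10**6)
    if a == b and a in "ACGT":
        return match
    return mismatch


def sw_matrices_naive(q: str, s: str, match=2, mismatch=-3, gap_open=5,
                      gap_extend=2):
    """Affine-gap local alignment DP from the textbook recurrences.

    H[i][j]: best alignment ending at (i, j); E: ending in a gap that
    consumes the subject; F: ditto for the query.  Returns
    (H, E, F, best, bi, bj) with best-cell ties at the smallest (i, j)."""
    m, n = len(q), len(s)
    go = gap_open + gap_extend
    ge = gap_extend
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        qa = q[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            h = max(
                0,
                H[i - 1][j - 1] + _score(qa, s[j - 1], match, mismatch),
                E[i][j],
                F[i][j],
            )
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    return H, E, F, best, bi, bj


def traceback_path_naive(H, E, F, q, s, bi, bj, match=2, mismatch=-3,
                         gap_open=5, gap_extend=2):
    """Traceback with the documented preference: diagonal, then gap
    consuming the subject, then gap consuming the query; gaps prefer
    re-opening.  Returns (forward steps [(ds, dq, dj, is_match)], i0, j0)."""
    go = gap_open + gap_extend
    ge = gap_extend
    i, j = bi, bj
    steps = []
    state = "H"
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            sc = _score(q[i - 1], s[j - 1], match, mismatch)
            if H[i - 1][j - 1] + sc == H[i][j]:
                steps.append((sc, 1, 1, sc == match))
                i, j = i - 1, j - 1
            elif E[i][j] == H[i][j]:
                state = "E"
            else:
                assert F[i][j] == H[i][j], "oracle traceback failed"
                state = "F"
        elif state == "E":
            if H[i][j - 1] - go == E[i][j]:
                steps.append((-go, 0, 1, False))
                j -= 1
                state = "H"
            else:
                steps.append((-ge, 0, 1, False))
                j -= 1
        else:
            if H[i - 1][j] - go == F[i][j]:
                steps.append((-go, 1, 0, False))
                i -= 1
                state = "H"
            else:
                steps.append((-ge, 1, 0, False))
                i -= 1
    steps.reverse()
    return steps, i, j


def split_xdrop_naive(steps, x_dropoff):
    """Cut the path where the running score drops more than x_dropoff below
    its running maximum; skip negative prefixes.  Returns
    (start, end_inclusive, score) triples."""
    segs = []
    seg_start, c, cmax, tmax = 0, 0, 0, -1
    for t, (ds, _dq, _dj, _m) in enumerate(steps):
        c += ds
        if c > cmax:
            cmax, tmax = c, t
        if c < 0 or c < cmax - x_dropoff:
            if cmax > 0 and tmax >= seg_start:
                segs.append((seg_start, tmax, cmax))
            seg_start, c, cmax, tmax = t + 1, 0, 0, t
    if cmax > 0 and tmax >= seg_start:
        segs.append((seg_start, tmax, cmax))
    return segs


def _seg_stats_naive(steps, i0, j0, seg):
    start, end, score = seg
    qpos, spos = i0, j0
    for _ds, dq, dj, _m in steps[:start]:
        qpos += dq
        spos += dj
    q_start, s_start = qpos + 1, spos + 1
    matches = mismatches = gap_cols = gap_opens = 0
    prev_gap = 0
    for _ds, dq, dj, is_match in steps[start:end + 1]:
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
        "q_start": q_start, "q_end": qpos, "s_start": s_start, "s_end": spos,
        "matches": matches, "mismatches": mismatches, "gap_opens": gap_opens,
        "align_length": matches + mismatches + gap_cols, "score": score,
    }


def oracle_hits(q: str, s: str, min_score: int, match=2, mismatch=-3,
                gap_open=5, gap_extend=2, x_dropoff=40, max_rounds=64):
    """All hits of q against s (plus strand): repeated naive SW; each round
    reports the X-drop segments of the best path that reach min_score and
    masks the full explored subject span."""
    s_work = list(s)
    out = []
    for _ in range(max_rounds):
        sw = "".join(s_work)
        H, E, F, best, bi, bj = sw_matrices_naive(q, sw, match, mismatch,
                                                  gap_open, gap_extend)
        if best < min_score:
            break
        steps, i0, j0 = traceback_path_naive(H, E, F, q, sw, bi, bj, match,
                                             mismatch, gap_open, gap_extend)
        for seg in split_xdrop_naive(steps, x_dropoff):
            tb = _seg_stats_naive(steps, i0, j0, seg)
            if tb["score"] >= min_score:
                out.append(tb)
        for k in range(j0, bj):
            s_work[k] = MASK
    return out


# ----------------------------------------------------------------- misc


def karlin_evalue(score: float, m: int, n: int, K=0.41, lam=0.625) -> float:
    return K * m * n * math.exp(-lam * score)


def grid_bruteforce(fractions, length_thresholds, presence_thresholds):
    """Exhaustive double-loop threshold grid over a fraction matrix
    (list of rows)."""
    n_samples = len(fractions)
    n_loci = len(fractions[0])
    rows = {}
    for L in length_thresholds:
        for P in presence_thresholds:
            n = 0
            for j in range(n_loci):
                good = sum(1 for i in range(n_samples) if fractions[i][j] >= L)
                if good / n_samples >= P:
                    n += 1
            rows[(L, P)] = n
    return rows


def classify_column_naive(column, missing=("-", "?", "N")):
    vals = [c.upper() for c in column if c.upper() not in missing]
    if len(set(vals)) <= 1:
        return "constant"
    counts = {}
    for v in vals:
        if v in "ACGT":
            counts[v] = counts.get(v, 0) + 1
    if len([1 for c in counts.values() if c >= 2]) >= 2:
        return "parsimony_informative"
    return "variable_singleton"


def trim_naive(taxa, rows, max_missing=0.30, missing=("-", "?", "N")):
    """Two-phase trim: rows on original columns, then columns on kept rows."""
    def miss_frac_row(r):
        return sum(1 for c in r if c in missing) / len(r)

    kept = [(t, r) for t, r in zip(taxa, rows) if miss_frac_row(r) <= max_missing]
    if not kept:
        return [], []
    ncol = len(rows[0])
    keep_cols = []
    for j in range(ncol):
        mf = sum(1 for _, r in kept if r[j] in missing) / len(kept)
        if mf <= max_missing:
            keep_cols.append(j)
    out_rows = ["".join(r[j] for j in keep_cols) for _, r in kept]
    return [t for t, _ in kept], out_rows
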