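"""Hit model, tabular I/O and the built-in local aligner."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import oracle_hits
from probeforge.seqio import SequenceRecord, reverse_complement
from probeforge.simsearch import (
    Hit,
    HitTableFormatError,
    SearchParams,
    local_search,
    percent_divergence,
    read_hit_table,
    search_pair,
    write_hit_table,
)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# ----------------------------------------------------------- tabular I/O


def test_read_hit_table_line(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text("q1\ts1\t83.50\t250\t40\t2\t1\t250\t1000\t1249\t1e-50\t180.3\n")
    (h,) = read_hit_table(p)
    assert h.percent_identity == 83.5 and h.align_length == 250
    assert h.strand == "+" and h.s_lo == 1000


def test_read_hit_table_empty(tmp_path):
    p = tmp_path / "e.tsv"
    p.write_text("")
    assert read_hit_table(p) == []


def test_hit_table_wrong_columns(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("a\tb\tc\n")
    with pytest.raises(HitTableFormatError, match=":1"):
        read_hit_table(p)


def test_hit_table_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    hits = []
    for i in range(20):
        qs, qe = sorted(rng.integers(1, 500, 2).tolist())
        ss, se = sorted(rng.integers(1, 5000, 2).tolist())
        if i % 3 == 0:
            ss, se = se, ss  # minus strand
        hits.append(Hit(f"q{i}", f"s{i%4}", round(float(rng.uniform(70, 100)), 2),
                        int(rng.integers(50, 400)), int(rng.integers(0, 40)),
                        int(rng.integers(0, 5)), qs, qe + 1, ss, se + 1,
                        1e-30, round(float(rng.uniform(50, 500)), 1)))
    p = tmp_path / "rt.tsv"
    write_hit_table(hits, p)
    back = read_hit_table(p)
    for a, b in zip(hits, back):
        assert (a.query_id, a.subject_id, a.percent_identity, a.align_length,
                a.mismatches, a.gap_opens, a.q_start, a.q_end, a.s_start,
                a.s_end, a.bit_score) == (
                b.query_id, b.subject_id, b.percent_identity, b.align_length,
                b.mismatches, b.gap_opens, b.q_start, b.q_end, b.s_start,
                b.s_end, b.bit_score)
    write_hit_table(back, tmp_path / "rt2.tsv")
    assert p.read_text() == (tmp_path / "rt2.tsv").read_text()


# ----------------------------------------------------------- the engine


def test_exact_substring_hit():
    rng = np.random.default_rng(0)
    sub = _rand_seq(rng, 2000)
    q = sub[500:600]
    hits = [h for h in search_pair(SequenceRecord("q", q), SequenceRecord("s", sub))
            if h.strand == "+"]
    assert len(hits) == 1
    h = hits[0]
    assert (h.percent_identity, h.align_length, h.q_start, h.q_end) == (100.0, 100, 1, 100)
    assert (h.s_start, h.s_end) == (501, 600)


def test_no_shared_words_no_hits():
    q = "AC" * 30                      # no word shared with s on either strand
    s = "GA" * 200
    assert search_pair(SequenceRecord("q", q), SequenceRecord("s", s)) == []


def test_all_n_query_warns_and_yields_nothing():
    with pytest.warns(UserWarning, match="unambiguous"):
        hits = local_search([SequenceRecord("q", "N" * 100)],
                            [SequenceRecord("s", "ACGT" * 100)])
    assert hits == []


def test_engine_equals_oracle_on_random_pairs():
    """Seeded spot-check of engine == brute-force DP (the full 200-pair
    comparison runs in the acceptance suite)."""
    rng = np.random.default_rng(42)
    params = SearchParams(min_raw_score=25, e_value_max=1e3, word_size=0)
    for trial in range(25):
        a = _rand_seq(rng, int(rng.integers(50, 150)))
        b = _rand_seq(rng, int(rng.integers(60, 220)))
        if trial % 2:
            frag = list(a[5:5 + min(70, len(a) - 5)])
            for k in range(len(frag)):
                if rng.random() < 0.1:
                    frag[k] = str(rng.choice(list("ACGT")))
            pos = int(rng.integers(0, len(b) - len(frag)))
            b = b[:pos] + "".join(frag) + b[pos + len(frag):]
        thr = params.min_score_for(len(a), len(b))
        want = sorted((t["q_start"], t["q_end"], t["s_start"], t["s_end"], t["score"])
                      for t in oracle_hits(a, b, thr))
        got = sorted((h.q_start, h.q_end, h.s_start, h.s_end, h.score)
                     for h in search_pair(SequenceRecord("q", a),
                                          SequenceRecord("s", b), params)
                     if h.strand == "+")
        assert got == want


def test_seeded_path_equals_exhaustive_path_on_planted_locus():
    """The windowed 11-mer search must find the same hits as exhaustive DP
    when homology is realistic (high-identity planted copies)."""
    rng = np.random.default_rng(9)
    genome = _rand_seq(rng, 6000)
    insert = list(_rand_seq(rng, 400))
    for k in range(len(insert)):
        if rng.random() < 0.05:
            insert[k] = str(rng.choice(list("ACGT")))
    genome = genome[:2500] + "".join(insert) + genome[2900:]
    q = SequenceRecord("q", "".join(_rand_seq(rng, 0)) + genome[2500:2900])
    s = SequenceRecord("s", genome)
    seeded = search_pair(q, s, SearchParams())
    exhaustive = search_pair(q, s, SearchParams(word_size=0))
    key = lambda h: (h.q_start, h.q_end, h.s_start, h.s_end, h.score)
    assert sorted(map(key, seeded)) == sorted(map(key, exhaustive))


def test_strand_symmetry():
    """Searching the reverse complement of the subject yields the same hits
    with subject coordinates swapped."""
    rng = np.random.default_rng(4)
    sub = _rand_seq(rng, 800)
    q = SequenceRecord("q", sub[100:220])
    n = len(sub)
    fwd = search_pair(q, SequenceRecord("s", sub))
    rev = search_pair(q, SequenceRecord("s", reverse_complement(sub)))
    fwd_key = sorted((h.q_start, h.q_end, h.s_start, h.s_end, h.score) for h in fwd)
    rev_key = sorted((h.q_start, h.q_end, n - h.s_start + 1, n - h.s_end + 1, h.score)
                     for h in rev)
    assert fwd_key == rev_key


@given(st.integers(1, 30))
def test_evalue_monotonicity(exp):
    """Lowering e_value_max never adds hits."""
    rng = np.random.default_rng(77)
    sub = _rand_seq(rng, 500)
    q = SequenceRecord("q", sub[50:150])
    s = SequenceRecord("s", sub)
    loose = search_pair(q, s, SearchParams(e_value_max=10.0 ** -exp, min_raw_score=20))
    tight = search_pair(q, s, SearchParams(e_value_max=10.0 ** -(exp + 5), min_raw_score=20))
    loose_keys = {(h.q_start, h.q_end, h.s_start, h.s_end) for h in loose}
    tight_keys = {(h.q_start, h.q_end, h.s_start, h.s_end) for h in tight}
    assert tight_keys <= loose_keys


def test_output_order_is_deterministic():
    rng = np.random.default_rng(12)
    sub = _rand_seq(rng, 3000)
    queries = [SequenceRecord(f"q{i}", sub[i * 300:i * 300 + 150]) for i in range(4)]
    subj = [SequenceRecord("s", sub)]
    h1 = local_search(queries, subj)
    h2 = local_search(list(queries), [SequenceRecord("s", sub)])
    assert [(a.query_id, a.s_start, a.bit_score) for a in h1] == \
           [(a.query_id, a.s_start, a.bit_score) for a in h2]
    assert h1 == sorted(h1, key=lambda h: (h.query_id, -h.bit_score, h.subject_id, h.s_lo))


# ----------------------------------------------------- percent divergence


def test_divergence_identical_sequences():
    assert percent_divergence("ACGT" * 50, "ACGT" * 50) == (0.0, True)


def test_divergence_single_substitution():
    rng = np.random.default_rng(6)
    a = _rand_seq(rng, 100)
    pos = 50
    alt = next(c for c in "ACGT" if c != a[pos])
    b = a[:pos] + alt + a[pos + 1:]
    div, aligned = percent_divergence(a, b)
    assert aligned and div == pytest.approx(1.0)


def test_divergence_no_alignment_flagged():
    div, aligned = percent_divergence("A" * 40, "G" * 40)
    assert (div, aligned) == (100.0, False)


def test_divergence_matches_bruteforce_dp():
    rng = np.random.default_rng(8)
    a = _rand_seq(rng, 150)
    b = list(a)
    for k in range(len(b)):
        if rng.random() < 0.07:
            b[k] = str(rng.choice(list("ACGT")))
    b = "".join(b)
    (tb,) = oracle_hits(a, b, 40)[:1]
    expected = 100.0 - 100.0 * tb["matches"] / tb["align_length"]
    div, aligned = percent_divergence(a, b)
    assert aligned and div == pytest.approx(expected)
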