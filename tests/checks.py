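"""Desk-scale verification routines shared by the acceptance tests and
scripts/acceptance.py.  Each function recomputes a quantity from scratch by
running the package on freshly generated inputs and returns plain numbers."""

from __future__ import annotations

import dataclasses

import numpy as np

from oracles import (
    classify_column_naive,
    grid_bruteforce,
    oracle_hits,
    trim_naive,
)
from probeforge.alnstats import site_classification, trim_alignment
from probeforge.probedesign import DesignConfig, design_probe_set, retained_query_ids
from probeforge.recovery import (
    LENGTH_THRESHOLDS,
    PRESENCE_THRESHOLDS,
    RecoveryMatrix,
    threshold_summary,
)
from probeforge.refopt import build_optimized_references
from probeforge.seqio import SequenceRecord
from probeforge.simsearch import SearchParams, search_pair
from probeforge.synthfix import SimConfig, simulate_annotated_genome


def planted_recovery(seeds) -> dict:
    """Design cascade on synthetic genome pairs: false positives/negatives
    against the planted truth, summed over seeds."""
    fp = fn = n_qualifying = n_decoys = 0
    for seed in seeds:
        design = simulate_annotated_genome(SimConfig(seed=seed))
        tset, _ = design_probe_set(design.genome_a, design.genome_b,
                                   design.queries)
        got = retained_query_ids(tset)
        want = design.truth.retained_query_ids()
        fp += len(got - want)
        fn += len(want - got)
        n_qualifying += len(want)
        n_decoys += sum(1 for e in design.truth.entries if e.designed_violation)
    return {"false_positives": fp, "false_negatives": fn,
            "n_qualifying": n_qualifying, "n_decoys": n_decoys,
            "n_seeds": len(seeds)}


def engine_vs_oracle(seed: int, n_pairs: int = 200) -> dict:
    """Built-in aligner vs the exhaustive DP oracle on random pairs
    (plus planted homologies with substitutions and indels); counts pairs
    with identical hit sets and scores."""
    rng = np.random.default_rng(seed)
    params = SearchParams(min_raw_score=25, e_value_max=1e3, word_size=0)
    agree = 0
    for trial in range(n_pairs):
        if trial == n_pairs - 1:
            la, lb = 600, 1000          # one pair at the 1 kb size bound
        else:
            la = int(rng.integers(50, 180))
            lb = int(rng.integers(60, 240))
        a = "".join(rng.choice(list("ACGT"), la))
        b = "".join(rng.choice(list("ACGT"), lb))
        if trial % 2:
            frag = list(a[5:5 + min(100, la - 5)])
            out = []
            for ch in frag:
                r = rng.random()
                if r < 0.08:
                    out.append(str(rng.choice(list("ACGT"))))
                elif r < 0.10:
                    pass
                elif r < 0.12:
                    out.extend([ch, str(rng.choice(list("ACGT")))])
                else:
                    out.append(ch)
            pos = int(rng.integers(0, max(1, lb - len(out))))
            b = b[:pos] + "".join(out) + b[pos + len(out):]
        thr = params.min_score_for(len(a), len(b))
        want = sorted((t["q_start"], t["q_end"], t["s_start"], t["s_end"],
                       t["score"]) for t in oracle_hits(a, b, thr))
        got = sorted((h.q_start, h.q_end, h.s_start, h.s_end, h.score)
                     for h in search_pair(SequenceRecord("q", a),
                                          SequenceRecord("s", b), params)
                     if h.strand == "+")
        agree += int(got == want)
    return {"n_pairs": n_pairs, "n_agree": agree,
            "agreement_pct": 100.0 * agree / n_pairs}


def grid_vs_bruteforce(seed: int, n_matrices: int = 50) -> dict:
    """threshold_summary vs the exhaustive double loop on random 20x50
    recovery matrices; also checks grid monotonicity."""
    rng = np.random.default_rng(seed)
    agree = monotone = 0
    for _ in range(n_matrices):
        rec = rng.integers(0, 130, size=(20, 50)).astype(float)
        m = RecoveryMatrix([f"s{i}" for i in range(20)],
                           [f"l{j}" for j in range(50)], rec,
                           np.full(50, 100.0))
        s = threshold_summary(m)
        want = grid_bruteforce(m.fraction.tolist(), LENGTH_THRESHOLDS,
                               PRESENCE_THRESHOLDS)
        agree += int({k: v[0] for k, v in s.rows.items()} == want)
        monotone += int(s.monotone())
    return {"n_matrices": n_matrices, "n_agree": agree, "n_monotone": monotone}


def alnstats_vs_oracles(seed: int, n_columns: int = 1000,
                        n_alignments: int = 100) -> dict:
    """Site classification and row-then-column trimming vs naive oracles."""
    from probeforge.alnstats import AlignmentMatrix

    rng = np.random.default_rng(seed)
    cls_agree = 0
    for _ in range(n_columns):
        col = rng.choice(list("ACGT-?NRY"), size=int(rng.integers(4, 16)),
                         p=[.19, .19, .19, .19, .08, .05, .05, .03, .03])
        cls_agree += int(site_classification(col) == classify_column_naive(col))
    trim_agree = 0
    for _ in range(n_alignments):
        nt = int(rng.integers(4, 12))
        nc = int(rng.integers(10, 60))
        rows = ["".join(rng.choice(list("ACGT-?N"), nc,
                                   p=[.2, .2, .2, .2, .1, .05, .05]))
                for _ in range(nt)]
        t = trim_alignment(AlignmentMatrix.from_strings(
            [f"t{i}" for i in range(nt)], rows))
        taxa_naive, rows_naive = trim_naive([f"t{i}" for i in range(nt)], rows)
        got = (t.taxa, ["".join(r) for r in t.data]) if not t.is_empty else ([], [])
        trim_agree += int(got == (taxa_naive, rows_naive))
    return {
        "n_columns": n_columns, "n_columns_agree": cls_agree,
        "n_alignments": n_alignments, "n_trim_agree": trim_agree,
    }


def refopt_exact(seed: int = 0) -> dict:
    """Reference optimization on the hand-assembled toy: byte-exact match
    plus the one-record-per-locus invariant."""
    from toydata import build_refopt_toy

    universal, genome, features, expected = build_refopt_toy(seed)
    best, group, result = build_optimized_references(
        universal, [("G1", genome, features)])
    exact = int(
        {r.id: r.seq for r in best} == {k: v["best"] for k, v in expected.items()}
        and {r.id: r.seq for r in group} == {k: v["group"] for k, v in expected.items()}
    )
    one_per_locus = int(len(best) == len(expected)
                        and len({r.id for r in best}) == len(best))
    return {"byte_exact": exact, "one_record_per_locus": one_per_locus,
            "n_loci": len(best)}


def cascade_monotonicity(seed: int, n_configs: int = 20) -> dict:
    """Stricter thresholds never increase the number of retained queries
    (checked around the design defaults on one synthetic dataset with
    precomputed hits)."""
    from probeforge.simsearch import local_search

    design = simulate_annotated_genome(SimConfig(seed=seed))
    sp = SearchParams()
    hits_a = local_search(design.queries, design.genome_a, sp)
    hits_b = local_search(design.queries, design.genome_b, sp)
    base, _ = design_probe_set(design.genome_a, design.genome_b, design.queries,
                               hits_a=hits_a, hits_b=hits_b)
    n_base = len(retained_query_ids(base))
    rng = np.random.default_rng(seed + 1)
    violations = 0
    for _ in range(n_configs):
        cfg = DesignConfig(
            min_hit_len=int(rng.integers(70, 120)),
            min_hit_query_frac=float(rng.uniform(0.10, 0.25)),
            min_hit_identity=float(rng.uniform(80, 94)),
            max_cluster_gap=int(rng.integers(2000, 10_001)),
            max_loci_per_query_initial=int(rng.integers(2, 7)),
            min_sum_coverage=float(rng.uniform(90, 99)),
            # upper bound 95: above it the summed-identity filter can
            # delete copies of a multigene family and rescue the query
            # from the locus-count limit (the documented inversion)
            min_sum_identity=float(rng.uniform(90, 95)),
            min_single_hit_len=int(rng.integers(100, 200)),
            max_intron_len=int(rng.integers(300, 1201)),
            max_loci_per_query=int(rng.integers(1, 3)),
            min_interlocus_divergence=float(rng.uniform(6, 12)),
            max_ortholog_divergence=float(rng.uniform(5, 15)),
            min_exon_len=int(rng.integers(80, 150)),
        )
        tset, _ = design_probe_set(design.genome_a, design.genome_b,
                                   design.queries, cfg,
                                   hits_a=hits_a, hits_b=hits_b)
        if len(retained_query_ids(tset)) > n_base:
            violations += 1
    return {"n_configs": n_configs, "violations": violations,
            "n_retained_default": n_base}
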