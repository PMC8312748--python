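"""Alignment post-processing and per-alignment statistics.

Implements the missing-data trim used before gene-tree estimation (every
row, then every column, with more than 30% missing data removed -- one
pass each, no fixpoint iteration), the minimum-taxa discard, and
variable / parsimony-informative site counts in the AMAS convention.

Missing symbols are '-', '?' and 'N'.  Other IUPAC ambiguity codes count
as data for the missing-data trim and the variability tally, but are
treated as missing when counting parsimony-informative states (a
conservative choice; stated in reports).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from Bio import AlignIO

__all__ = [
    "AlignmentMatrix",
    "AlignmentStats",
    "read_alignment",
    "trim_alignment",
    "discard_small",
    "site_classification",
    "alignment_summary",
    "batch_summary",
]

MISSING = frozenset("-?N")
_UNAMBIG = frozenset("ACGT")


@dataclass
class AlignmentMatrix:
    """A rectangular multiple sequence alignment (taxa x columns)."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_cols) of single characters ('<U1')
    missing: frozenset = MISSING

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("alignment matrix shape inconsistent with taxa")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.data.size == 0

    def missing_mask(self) -> np.ndarray:
        mask = np.zeros(self.data.shape, dtype=bool)
        for sym in self.missing:
            mask |= self.data == sym
        return mask

    @classmethod
    def from_strings(cls, taxa: Sequence[str], rows: Sequence[str]) -> "AlignmentMatrix":
        if len(set(map(len, rows))) > 1:
            raise ValueError("alignment rows have unequal lengths")
        arr = np.array([list(r.upper()) for r in rows], dtype="<U1")
        return cls(list(taxa), arr)


def read_alignment(path: str | Path, fmt: str = "fasta") -> AlignmentMatrix:
    aln = AlignIO.read(str(path), fmt)
    return AlignmentMatrix.from_strings(
        [rec.id for rec in aln], [str(rec.seq) for rec in aln]
    )


def trim_alignment(aln: AlignmentMatrix, max_missing: float = 0.30) -> AlignmentMatrix:
    """Remove rows, then columns, with more than ``max_missing`` missing data.

    Row fractions are computed on the original columns; column fractions on
    the retained rows.  Exactly one pass each -- the procedure is
    order-dependent and is *not* iterated to a fixpoint.  A fully emptied
    alignment is returned as a 0x0 matrix (flagged by ``is_empty``).
    """
    if aln.is_empty:
        return aln
    miss = aln.missing_mask()
    row_frac = miss.mean(axis=1)
    keep_rows = row_frac <= max_missing
    if not keep_rows.any():
        return AlignmentMatrix([], np.empty((0, 0), dtype="<U1"), aln.missing)
    data = aln.data[keep_rows]
    col_frac = miss[keep_rows].mean(axis=0)
    keep_cols = col_frac <= max_missing
    data = data[:, keep_cols]
    taxa = [t for t, k in zip(aln.taxa, keep_rows) if k]
    if data.shape[1] == 0:
        return AlignmentMatrix([], np.empty((0, 0), dtype="<U1"), aln.missing)
    return AlignmentMatrix(taxa, data, aln.missing)


def discard_small(
    alignments: Iterable[AlignmentMatrix], min_taxa: int = 4
) -> list[AlignmentMatrix]:
    """Drop alignments with fewer than ``min_taxa`` sequences."""
    return [a for a in alignments if a.n_taxa >= min_taxa]


def site_classification(column: Sequence[str], missing: frozenset = MISSING) -> str:
    """Classify one alignment column.

    Ignoring missing symbols: ``constant`` if at most one distinct state
    remains; ``parsimony_informative`` if at least two states (unambiguous
    bases only) each occur in at least two sequences; otherwise
    ``variable_singleton``.
    """
    states = [c.upper() for c in column if c.upper() not in missing]
    if len(set(states)) <= 1:
        return "constant"
    counts: dict[str, int] = {}
    for s in states:
        if s in _UNAMBIG:
            counts[s] = counts.get(s, 0) + 1
    n_common = sum(1 for v in counts.values() if v >= 2)
    if n_common >= 2:
        return "parsimony_informative"
    return "variable_singleton"


def _round1(x: float) -> float:
    """Half-up rounding to one decimal, applied only at report time."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class AlignmentStats:
    n_taxa: int
    length_bp: int
    n_variable: int
    prop_variable: float            # percent, full precision
    n_parsimony_informative: int
    prop_parsimony_informative: float

    def report(self) -> dict:
        return {
            "n_taxa": self.n_taxa,
            "length_bp": self.length_bp,
            "n_variable": self.n_variable,
            "pct_variable": _round1(self.prop_variable),
            "n_parsimony_informative": self.n_parsimony_informative,
            "pct_parsimony_informative": _round1(self.prop_parsimony_informative),
        }


def alignment_summary(aln: AlignmentMatrix) -> AlignmentStats:
    """Counts of variable and parsimony-informative sites plus proportions."""
    if aln.is_empty:
        return AlignmentStats(0, 0, 0, 0.0, 0, 0.0)
    n_var = n_pi = 0
    for j in range(aln.length):
        cls = site_classification(aln.data[:, j], aln.missing)
        if cls != "constant":
            n_var += 1
        if cls == "parsimony_informative":
            n_pi += 1
    L = aln.length
    return AlignmentStats(
        n_taxa=aln.n_taxa,
        length_bp=L,
        n_variable=n_var,
        prop_variable=100.0 * n_var / L,
        n_parsimony_informative=n_pi,
        prop_parsimony_informative=100.0 * n_pi / L,
    )


def batch_summary(alignments: Sequence[AlignmentMatrix]) -> dict:
    """Per-alignment stats plus min/avg/max rows and batch totals."""
    stats = [alignment_summary(a) for a in alignments]
    if not stats:
        return {"per_alignment": [], "n_alignments": 0}

    def _agg(vals):
        return {
            "min": min(vals),
            "avg": float(np.mean(vals)),
            "max": max(vals),
        }

    return {
        "per_alignment": stats,
        "n_alignments": len(stats),
        "avg_n_taxa": float(np.mean([s.n_taxa for s in stats])),
        "length_bp": _agg([s.length_bp for s in stats]),
        "total_length_bp": int(sum(s.length_bp for s in stats)),
        "n_variable": _agg([s.n_variable for s in stats]),
        "pct_variable": _agg([s.prop_variable for s in stats]),
        "n_parsimony_informative": _agg([s.n_parsimony_informative for s in stats]),
        "pct_parsimony_informative": _agg([s.prop_parsimony_informative for s in stats]),
        "total_parsimony_informative": int(
            sum(s.n_parsimony_informative for s in stats)
        ),
    }


def write_batch_tsv(alignments: Sequence[AlignmentMatrix], names: Sequence[str],
                    out: str | Path) -> None:
    with open(out, "w") as fh:
        fh.write("alignment\tn_taxa\tlength_bp\tn_variable\tpct_variable\t"
                 "n_parsimony_informative\tpct_parsimony_informative\n")
        for name, aln in zip(names, alignments):
            r = alignment_summary(aln).report()
            fh.write(f"{name}\t{r['n_taxa']}\t{r['length_bp']}\t{r['n_variable']}\t"
                     f"{r['pct_variable']}\t{r['n_parsimony_informative']}\t"
                     f"{r['pct_parsimony_informative']}\n")
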