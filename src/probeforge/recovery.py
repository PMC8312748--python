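"""Locus-recovery accounting for hybrid-capture experiments.

Consumes a per-sample x per-locus recovered-length table (the HybPiper
``seq_lengths`` dialect: first row locus ids, second row reference target
lengths, then one row per sample), converts recovered lengths into
fractions of the target length, and summarises data completeness over a
grid of target-length and accessions-presence thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RecoveryMatrix",
    "ThresholdSummary",
    "load_seq_lengths",
    "mean_target_length",
    "enrichment_efficiency",
    "zero_data_loci",
    "threshold_summary",
    "export_heatmap",
    "plot_heatmap",
]

LENGTH_THRESHOLDS = (0.25, 0.50, 0.75)
PRESENCE_THRESHOLDS = (0.50, 0.75)


@dataclass
class RecoveryMatrix:
    """Recovered lengths and fractions, samples x loci.

    ``fraction = recovered / target`` capped at 1.0 (assembled contigs can
    exceed the reference length).
    """

    samples: list[str]
    loci: list[str]
    recovered_len: np.ndarray      # (n_samples, n_loci) float
    target_len: np.ndarray         # (n_loci,) float

    fraction: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.recovered_len.shape != (len(self.samples), len(self.loci)):
            raise ValueError("recovered_len shape inconsistent with sample/locus ids")
        if np.any(self.target_len <= 0):
            raise ValueError("target lengths must be positive")
        if np.any(self.recovered_len < 0):
            raise ValueError("recovered lengths must be non-negative")
        frac = self.recovered_len / self.target_len[None, :]
        if np.any(frac > 1.0):
            warnings.warn("recovered length exceeds target length; fraction capped at 1.0")
        self.fraction = np.minimum(frac, 1.0)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fraction, index=self.samples, columns=self.loci)


@dataclass
class ThresholdSummary:
    """Locus counts over the (length, presence) threshold grid."""

    rows: dict[tuple[float, float], tuple[int, float]]
    n_zero_data_loci: int
    pct_zero_data_loci: float
    n_loci: int

    def monotone(self) -> bool:
        """Counts must be non-increasing in both thresholds."""
        Ls = sorted({L for L, _ in self.rows})
        Ps = sorted({P for _, P in self.rows})
        for P in Ps:
            for a, b in zip(Ls, Ls[1:]):
                if self.rows[(b, P)][0] > self.rows[(a, P)][0]:
                    return False
        for L in Ls:
            for a, b in zip(Ps, Ps[1:]):
                if self.rows[(L, b)][0] > self.rows[(L, a)][0]:
                    return False
        return True


def load_seq_lengths(path: str | Path) -> RecoveryMatrix:
    """Read a HybPiper-style seq_lengths TSV."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    if df.shape[0] < 1:
        raise ValueError(f"{path}: no reference-length row")
    try:
        values = df.astype(float)
    except ValueError as exc:
        bad = df.map(lambda v: not _is_number(v))
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        ) from exc
    target = values.iloc[0].to_numpy()
    recovered = values.iloc[1:]
    return RecoveryMatrix(
        samples=[str(s) for s in recovered.index],
        loci=[str(c) for c in df.columns],
        recovered_len=recovered.to_numpy(dtype=float),
        target_len=target.astype(float),
    )


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def mean_target_length(representative_lengths: Sequence[float]) -> float:
    """Average representative length of a multi-representative locus."""
    if not representative_lengths:
        raise ValueError("no representative lengths given")
    return float(np.mean(representative_lengths))


def enrichment_efficiency(mapped_reads: int, total_reads: int) -> float:
    """Percentage of reads mapping to target loci."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if mapped_reads > total_reads:
        raise ValueError("mapped_reads exceeds total_reads")
    return 100.0 * mapped_reads / total_reads


def zero_data_loci(matrix: RecoveryMatrix) -> tuple[int, float]:
    """Loci with zero recovered length in every sample."""
    zero = np.all(matrix.recovered_len == 0, axis=0)
    n = int(zero.sum())
    return n, 100.0 * n / matrix.n_loci


def threshold_summary(
    matrix: RecoveryMatrix,
    length_thresholds: Sequence[float] = LENGTH_THRESHOLDS,
    presence_thresholds: Sequence[float] = PRESENCE_THRESHOLDS,
    joint: bool = True,
) -> ThresholdSummary:
    """Count loci passing each (length, presence) threshold pair.

    A locus counts at (L, P) iff the proportion of samples whose recovered
    fraction is >= L is itself >= P.  With ``joint=False`` presence is
    evaluated as "any data" (fraction > 0) rather than at level L.
    """
    rows: dict[tuple[float, float], tuple[int, float]] = {}
    frac = matrix.fraction
    for L in length_thresholds:
        ok = frac >= L if joint else frac > 0
        presence = ok.mean(axis=0)
        for P in presence_thresholds:
            n = int((presence >= P).sum())
            rows[(L, P)] = (n, 100.0 * n / matrix.n_loci)
    n_zero, pct_zero = zero_data_loci(matrix)
    return ThresholdSummary(rows, n_zero, pct_zero, matrix.n_loci)


def export_heatmap(matrix: RecoveryMatrix, out: str | Path) -> None:
    """Write the fraction matrix as TSV (samples as rows, loci as columns,
    locus order preserved from the reference)."""
    matrix.to_frame().to_csv(out, sep="\t", index_label="sample")


def import_heatmap(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def plot_heatmap(matrix: RecoveryMatrix, out: str | Path) -> None:
    """Optional graphical heatmap (one row per sample, shaded by fraction)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, matrix.n_loci * 0.08), max(2, matrix.n_samples * 0.25))
    )
    im = ax.imshow(matrix.fraction, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_yticks(range(matrix.n_samples), matrix.samples, fontsize=6)
    ax.set_xlabel("locus")
    fig.colorbar(im, ax=ax, label="recovered fraction of target length")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def write_grid_tsv(summary: ThresholdSummary, out: str | Path) -> None:
    with open(out, "w") as fh:
        fh.write("length_threshold\tpresence_threshold\tn_loci\tpct_loci\n")
        for (L, P), (n, pct) in sorted(summary.rows.items()):
            fh.write(f"{L}\t{P}\t{n}\t{pct:.1f}\n")
        fh.write(f"# zero-data loci: {summary.n_zero_data_loci} "
                 f"({summary.pct_zero_data_loci:.1f}%)\n")
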