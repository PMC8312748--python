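"""Hand-assembled toy data shared by the refopt tests and the acceptance
script: a five-locus universal probe set with three representatives per
locus, a toy annotated genome holding the orthologs, and the expected
trimmed reference sequences assembled by hand from the construction."""

from __future__ import annotations

import numpy as np

from probeforge.seqio import AnnotationFeature, SequenceRecord, reverse_complement


def build_refopt_toy(seed: int = 0):
    """Returns (universal_records, genome_records, features, expected).

    ``expected`` maps locus id -> dict(best, group, rep_id) with the
    hand-assembled trimmed concatenations.

    Construction: five two-exon genes on one chromosome (gene 4 on the
    minus strand).  Per locus, representative ``a`` is the exact exon
    concatenation (the longest hit and thus the expected choice),
    ``b`` is a 10%-mutated copy, ``c`` a truncated copy.  For locus 3,
    representative ``a`` covers exon 1 plus only the first 60 bp of
    exon 2, so the trimmed genome concatenation must lose the tail of
    exon 2.
    """
    rng = np.random.default_rng(seed)
    e1_len, e2_len, intron_len, spacer = 120, 150, 200, 300

    chrom_parts = []
    pos = 0
    genes = []
    for k in range(5):
        chrom_parts.append("".join(rng.choice(list("ACGT"), spacer)))
        pos += spacer
        e1 = "".join(rng.choice(list("ACGT"), e1_len))
        intron = "".join(rng.choice(list("ACGT"), intron_len))
        e2 = "".join(rng.choice(list("ACGT"), e2_len))
        strand = "-" if k == 4 else "+"
        coords = [(pos + 1, pos + e1_len),
                  (pos + e1_len + intron_len + 1, pos + e1_len + intron_len + e2_len)]
        chrom_parts.extend([e1, intron, e2])
        pos += e1_len + intron_len + e2_len
        genes.append({"e1": e1, "e2": e2, "coords": coords, "strand": strand})
    chrom = "".join(chrom_parts)
    genome = [SequenceRecord("chr1", chrom)]

    features = []
    for k, g in enumerate(genes):
        gid, tid = f"g{k}", f"t{k}"
        lo, hi = g["coords"][0][0], g["coords"][1][1]
        features.append(AnnotationFeature("chr1", "gene", lo, hi, g["strand"], gid,
                                          None, "protein_coding"))
        features.append(AnnotationFeature("chr1", "mRNA", lo, hi, g["strand"], tid, gid))
        for n, (a, b) in enumerate(g["coords"], 1):
            features.append(AnnotationFeature("chr1", "exon", a, b, g["strand"],
                                              f"{tid}.e{n}", tid))

    universal = []
    expected = {}
    for k, g in enumerate(genes):
        locus = f"{5000 + k}"
        concat = g["e1"] + g["e2"]
        if g["strand"] == "-":
            concat = reverse_complement(concat)
        if k == 3:
            rep_a = concat[: e1_len + 60]       # exon 1 + 60 bp of exon 2
            group_expected = concat[: e1_len + 60]
        else:
            rep_a = concat
            group_expected = concat
        mut = list(rep_a)  # representative b: mutated copy of a (never longer)
        idx = rng.choice(np.arange(5, len(mut) - 5), size=len(mut) // 10, replace=False)
        for i in idx:
            mut[i] = next(c for c in "ACGT" if c != mut[i])
        universal.append(SequenceRecord(f"taxA-{locus}", rep_a))
        universal.append(SequenceRecord(f"taxB-{locus}", "".join(mut)))
        universal.append(SequenceRecord(f"taxC-{locus}", concat[:140]))
        expected[locus] = {"best": rep_a, "group": group_expected,
                           "rep_id": f"taxA-{locus}"}
    return universal, genome, features, expected
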