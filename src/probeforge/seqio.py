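"""Sequence and annotation I/O: FASTA, GFF3, and exon-transcript extraction.

All genomic coordinates in this package are 1-based inclusive intervals,
the GFF3 convention.  Transcript sequences are assembled by concatenating
exon sequences in transcription order; minus-strand transcripts are the
reverse complement of the genomic exon concatenation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "AnnotationFeature",
    "TranscriptModel",
    "BiotypePolicy",
    "FastaFormatError",
    "GffFormatError",
    "read_fasta",
    "write_fasta",
    "parse_gff",
    "extract_exon_transcripts",
    "reverse_complement",
]


class FastaFormatError(ValueError):
    """Malformed FASTA input (empty sequence, duplicate id, ...)."""


class GffFormatError(ValueError):
    """Malformed GFF3 input (bad coordinates, wrong column count, ...)."""


_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA sequence.

    ``id`` must be unique within a collection; ``seq`` is upper-case DNA over
    the IUPAC alphabet.
    """

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


# GFF3 feature types recognised as transcript-level containers of exons.
TRANSCRIPT_TYPES = {
    "mRNA",
    "transcript",
    "lnc_RNA",
    "pseudogenic_transcript",
    "rRNA",
    "tRNA",
    "miRNA",
    "snoRNA",
    "snRNA",
    "ncRNA",
}

GENE_TYPES = {"gene", "pseudogene"}


@dataclass
class AnnotationFeature:
    """One GFF3 feature line (1-based inclusive coordinates)."""

    seq_id: str
    feature_type: str
    start: int
    end: int
    strand: str
    id: str
    parent_id: str | None = None
    biotype: str = ""
    attributes: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """Exon structure of one transcript plus its spliced sequence.

    ``exons`` are (start, end) genomic intervals in transcription order,
    i.e. descending genomic coordinates for minus-strand transcripts.
    """

    transcript_id: str
    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    concatenated_seq: str
    biotype: str = ""

    def __len__(self) -> int:
        return len(self.concatenated_seq)


# Default biotype vocabulary.  Matching is case-insensitive and alias-mapped
# because annotation dialects differ between assemblies (e.g. the SO term
# "pseudogenic_transcript" vs the attribute value "pseudogene").
DEFAULT_BIOTYPE_ALIASES = {
    "protein-coding": "protein_coding",
    "proteincoding": "protein_coding",
    "coding": "protein_coding",
    "mrna": "protein_coding",
    "lncrna": "lnc_rna",
    "lnc_rna": "lnc_rna",
    "lincrna": "lnc_rna",
    "long_noncoding_rna": "lnc_rna",
    "pseudogenic_transcript": "pseudogene",
    "transcribed_pseudogene": "pseudogene",
}


@dataclass
class BiotypePolicy:
    """Which gene biotypes yield transcripts, and which sequences to skip.

    The default keeps protein-coding genes, long non-coding RNAs and
    pseudogenes (including transcribed ones) and drops every other RNA class;
    organellar sequences are excluded by seq-id substring patterns because
    annotations rarely label them consistently.
    """

    include: frozenset[str] = frozenset({"protein_coding", "lnc_rna", "pseudogene"})
    exclude: frozenset[str] = frozenset(
        {"rrna", "trna", "mirna", "snorna", "snrna", "ncrna", "other_rna"}
    )
    aliases: dict = field(default_factory=lambda: dict(DEFAULT_BIOTYPE_ALIASES))
    organellar_seqid_patterns: tuple[str, ...] = ("plastid", "chloroplast", "mitochond")

    def __post_init__(self) -> None:
        if set(self.include) & set(self.exclude):
            raise ValueError("biotype policy include and exclude sets overlap")

    def normalize(self, biotype: str) -> str:
        b = biotype.strip().lower().replace("-", "_")
        return self.aliases.get(b, self.aliases.get(biotype.lower(), b))

    def passes(self, biotype: str, seq_id: str = "") -> bool:
        sid = seq_id.lower()
        if any(p in sid for p in self.organellar_seqid_patterns):
            return False
        return self.normalize(biotype) in self.include


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-FASTA file.

    Sequences are upper-cased; record order is preserved.  Raises
    :class:`FastaFormatError` on empty sequences or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty id")
        if len(rec.seq) == 0:
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA, wrapping lines at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _parse_attributes(col: str) -> dict:
    attrs: dict[str, str] = {}
    for chunk in col.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def parse_gff(path: str | Path) -> list[AnnotationFeature]:
    """Parse a GFF3 file into :class:`AnnotationFeature` records.

    Comment and pragma lines are skipped.  ``end < start`` raises
    :class:`GffFormatError`; a ``Parent`` pointing at an unknown ID produces a
    warning and the feature is kept orphaned.
    """
    feats: list[AnnotationFeature] = []
    ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                break  # trailing ##FASTA section
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffFormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attr_col = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_attributes(attr_col)
            fid = attrs.get("ID", f"{ftype}:{seq_id}:{start}-{end}:{lineno}")
            if end < start:
                raise GffFormatError(
                    f"{path}:{lineno}: feature {fid!r} has end {end} < start {start}"
                )
            biotype = attrs.get("biotype", attrs.get("gene_biotype", ""))
            feats.append(
                AnnotationFeature(
                    seq_id=seq_id,
                    feature_type=ftype,
                    start=start,
                    end=end,
                    strand=strand,
                    id=fid,
                    parent_id=attrs.get("Parent"),
                    biotype=biotype,
                    attributes=attrs,
                )
            )
            ids.add(fid)
    for f in feats:
        if f.parent_id is not None and f.parent_id not in ids:
            warnings.warn(
                f"{path}: feature {f.id!r} references unknown parent {f.parent_id!r}; kept orphaned",
                stacklevel=2,
            )
    return feats


def _infer_biotype(gene: AnnotationFeature | None, transcript: AnnotationFeature | None) -> str:
    for f in (transcript, gene):
        if f is not None and f.biotype:
            return f.biotype
    if transcript is not None and transcript.feature_type in TRANSCRIPT_TYPES:
        if transcript.feature_type in {"mRNA", "transcript"}:
            return "protein_coding"
        if transcript.feature_type == "lnc_RNA":
            return "lnc_rna"
        if transcript.feature_type == "pseudogenic_transcript":
            return "pseudogene"
        return transcript.feature_type.lower()
    if gene is not None and gene.feature_type == "pseudogene":
        return "pseudogene"
    return "protein_coding"


def extract_exon_transcripts(
    genome: Sequence[SequenceRecord],
    features: Sequence[AnnotationFeature],
    policy: BiotypePolicy | None = None,
) -> list[TranscriptModel]:
    """Concatenate annotated exons into transcript sequences.

    One model is emitted per transcript whose gene biotype passes ``policy``;
    genes with several transcripts yield several models.  Genes without
    explicit transcript children but with exons attached directly (flat
    annotation dialect) form one implicit transcript.  Minus-strand exon
    sequences are reverse complemented and ordered 5'->3' in transcription
    order.
    """
    policy = policy or BiotypePolicy()
    seqs = {r.id: r.seq for r in genome}
    by_id = {f.id: f for f in features}

    # exon lists per parent id
    exons_of: dict[str, list[AnnotationFeature]] = {}
    for f in features:
        if f.feature_type == "exon" and f.parent_id is not None:
            exons_of.setdefault(f.parent_id, []).append(f)

    models: list[TranscriptModel] = []

    def build(parent: AnnotationFeature, gene: AnnotationFeature | None) -> None:
        exons = exons_of.get(parent.id)
        if not exons:
            return
        biotype = _infer_biotype(gene, parent if parent.feature_type in TRANSCRIPT_TYPES else None)
        if not policy.passes(biotype, parent.seq_id):
            return
        if parent.seq_id not in seqs:
            raise GffFormatError(f"feature {parent.id!r} references unknown sequence {parent.seq_id!r}")
        chrom = seqs[parent.seq_id]
        ordered = sorted(exons, key=lambda e: e.start)
        for e in ordered:
            if e.end > len(chrom) or e.start < 1:
                raise GffFormatError(
                    f"exon {e.id!r} ({e.start}-{e.end}) exceeds bounds of {parent.seq_id!r}"
                )
        parts = [chrom[e.start - 1 : e.end] for e in ordered]
        concat = "".join(parts)
        strand = parent.strand if parent.strand in "+-" else "+"
        if strand == "-":
            concat = reverse_complement(concat)
            intervals = [(e.start, e.end) for e in reversed(ordered)]
        else:
            intervals = [(e.start, e.end) for e in ordered]
        gene_id = gene.id if gene is not None else parent.id
        models.append(
            TranscriptModel(
                transcript_id=parent.id,
                gene_id=gene_id,
                seq_id=parent.seq_id,
                strand=strand,
                exons=intervals,
                concatenated_seq=concat,
                biotype=policy.normalize(biotype),
            )
        )

    for f in features:
        if f.feature_type in TRANSCRIPT_TYPES:
            gene = by_id.get(f.parent_id) if f.parent_id else None
            build(f, gene)
        elif f.feature_type in GENE_TYPES and f.id in exons_of:
            # flat dialect: exons attached directly to the gene
            build(f, f)
    return models
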