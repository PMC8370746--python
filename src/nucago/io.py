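"""Readers and writers for BED6, GTF, FASTA and TSV with strict conventions.

Internal coordinates are uniformly 0-based half-open; GTF's 1-based inclusive
coordinates are converted on read and write. Gzip is handled transparently by
file suffix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

# Annotation categories in decreasing priority; intergenic is the implicit
# complement and is never stored as a feature.
CATEGORY_PRIORITY = (
    "CDS_exon",
    "UTR3",
    "UTR5",
    "pc_intron",
    "nc_exon",
    "nc_intron",
    "intergenic",
)
CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read a BED6 file into a list of intervals, preserving input order."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >=6 BED fields")
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if not 0 <= start < end:
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: unknown strand {strand!r}")
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], names=None) -> None:
    intervals = list(intervals)
    if names is None:
        names = [f"r{i}" for i in range(len(intervals))]
    with _open_text(path, "wt") as fh:
        for iv, name in zip(intervals, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GTF / annotation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedFeature:
    interval: GenomicInterval
    category: str
    gene_id: str
    is_mirna: bool = False


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def introns(self) -> list[GenomicInterval]:
        """Within-transcript gaps between consecutive exons."""
        exons = sorted(self.exons, key=lambda iv: iv.start)
        out = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
        return out


@dataclass
class Gene:
    gene_id: str
    gene_type: str
    interval: GenomicInterval


@dataclass
class AnnotationModel:
    """Gene annotation with categorised features derived from a GTF.

    ``features`` carries every categorised span (CDS exon, UTRs, introns,
    noncoding exons/introns); intergenic is the complement and never stored.
    ``mirna_loci`` is the subset of features belonging to miRNA genes.
    """

    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    features: list[AnnotatedFeature] = field(default_factory=list)

    @property
    def mirna_loci(self) -> list[AnnotatedFeature]:
        return [f for f in self.features if f.is_mirna]

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, value = part.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> AnnotationModel:
    """Parse an Ensembl/Gencode-dialect GTF into an :class:`AnnotationModel`.

    Introns are computed as within-transcript gaps between consecutive exons.
    UTRs use explicit ``five_prime_utr``/``three_prime_utr`` records when
    present, otherwise they are inferred from CDS vs exon extents.
    """
    model = AnnotationModel()
    explicit_utrs: list[tuple[str, GenomicInterval, str]] = []  # (cat, iv, gene)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GTF fields")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}: line {lineno}: missing gene_id attribute")
            gene_type = attrs.get("gene_type", attrs.get("gene_biotype", ""))
            iv = GenomicInterval(chrom, start, end, strand)
            if ftype == "gene":
                model.genes[gene_id] = Gene(gene_id, gene_type, iv)
                continue
            tx_id = attrs.get("transcript_id")
            if ftype == "transcript":
                if tx_id is None:
                    raise ParseError(
                        f"{path}: line {lineno}: transcript without transcript_id"
                    )
                model.transcripts.setdefault(
                    tx_id, Transcript(tx_id, gene_id, strand)
                )
                continue
            if ftype in ("exon", "CDS"):
                if tx_id is None:
                    raise ParseError(
                        f"{path}: line {lineno}: {ftype} without transcript_id"
                    )
                tx = model.transcripts.setdefault(
                    tx_id, Transcript(tx_id, gene_id, strand)
                )
                (tx.exons if ftype == "exon" else tx.cds).append(iv)
            elif ftype == "five_prime_utr":
                explicit_utrs.append(("UTR5", iv, gene_id))
            elif ftype == "three_prime_utr":
                explicit_utrs.append(("UTR3", iv, gene_id))
            # other feature types (start_codon, ...) are ignored
    _derive_features(model, explicit_utrs)
    return model


def _subtract(iv: GenomicInterval, lo: int, hi: int) -> list[tuple[int, int]]:
    """Parts of iv outside [lo, hi)."""
    parts = []
    if iv.start < lo:
        parts.append((iv.start, min(iv.end, lo)))
    if iv.end > hi:
        parts.append((max(iv.start, hi), iv.end))
    return parts


def _derive_features(model: AnnotationModel, explicit_utrs) -> None:
    feats: set[AnnotatedFeature] = set()
    genes_with_explicit_utr = {g for _c, _iv, g in explicit_utrs}
    for cat, iv, gene_id in explicit_utrs:
        feats.add(AnnotatedFeature(iv, cat, gene_id))
    for tx in model.transcripts.values():
        gene = model.genes.get(tx.gene_id)
        gene_type = gene.gene_type if gene else ""
        coding = bool(tx.cds) or gene_type == "protein_coding"
        is_mirna = gene_type == "miRNA"
        if coding:
            for iv in tx.cds:
                feats.add(AnnotatedFeature(iv, "CDS_exon", tx.gene_id))
            for iv in tx.introns():
                feats.add(AnnotatedFeature(iv, "pc_intron", tx.gene_id))
            if tx.cds and tx.gene_id not in genes_with_explicit_utr:
                cds_lo = min(c.start for c in tx.cds)
                cds_hi = max(c.end for c in tx.cds)
                for exon in tx.exons:
                    for s, e in _subtract(exon, cds_lo, cds_hi):
                        upstream = e <= cds_lo
                        cat = (
                            "UTR5"
                            if (upstream == (tx.strand == "+"))
                            else "UTR3"
                        )
                        feats.add(
                            AnnotatedFeature(
                                GenomicInterval(exon.chrom, s, e, exon.strand),
                                cat,
                                tx.gene_id,
                            )
                        )
        else:
            for iv in tx.exons:
                feats.add(AnnotatedFeature(iv, "nc_exon", tx.gene_id, is_mirna))
            for iv in tx.introns():
                feats.add(AnnotatedFeature(iv, "nc_intron", tx.gene_id, is_mirna))
    model.features = sorted(
        feats, key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end, f.category)
    )


def write_gtf(path, model: AnnotationModel) -> None:
    """Write genes/transcripts/exons/CDS back out in Ensembl-dialect GTF."""
    lines = []

    def fmt(ftype, iv, gene_id, gene_type, tx_id=None):
        attrs = f'gene_id "{gene_id}"; gene_type "{gene_type}";'
        if tx_id is not None:
            attrs += f' transcript_id "{tx_id}";'
        return (
            f"{iv.chrom}\tnucago\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\t{attrs}"
        )

    for gene in model.genes.values():
        lines.append(fmt("gene", gene.interval, gene.gene_id, gene.gene_type))
        for tx in model.transcripts_of(gene.gene_id):
            span = GenomicInterval(
                gene.interval.chrom,
                min(e.start for e in tx.exons),
                max(e.end for e in tx.exons),
                tx.strand,
            )
            lines.append(
                fmt("transcript", span, gene.gene_id, gene.gene_type, tx.transcript_id)
            )
            for exon in sorted(tx.exons, key=lambda iv: iv.start):
                lines.append(
                    fmt("exon", exon, gene.gene_id, gene.gene_type, tx.transcript_id)
                )
            for cds in sorted(tx.cds, key=lambda iv: iv.start):
                lines.append(
                    fmt("CDS", cds, gene.gene_id, gene.gene_type, tx.transcript_id)
                )
    with _open_text(path, "wt") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class FastaMap(dict):
    """Mapping of sequence id -> upper-case DNA string.

    ``alphabets`` records, per id, whether the original record used the RNA
    (U) or DNA (T) alphabet; U is normalised to T on read.
    """

    def __init__(self):
        super().__init__()
        self.alphabets: dict[str, str] = {}


def read_fasta(path) -> FastaMap:
    out = FastaMap()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
            seq = str(rec.seq).upper()
            out.alphabets[rec.id] = "RNA" if "U" in seq else "DNA"
            out[rec.id] = seq.replace("U", "T")
    return out


def write_fasta(path, sequences: dict, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def read_tsv(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(path, frame: pd.DataFrame, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)
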