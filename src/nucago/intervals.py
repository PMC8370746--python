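"""Strand-aware genomic intervals.

All coordinates in this package are 0-based half-open (BED convention).
GTF's 1-based inclusive coordinates are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware coordinate span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; expected '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def same_strand(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.strand == other.strand

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def union_span(self, other: "GenomicInterval") -> "GenomicInterval":
        """Smallest interval covering both (same chrom/strand required)."""
        if not self.same_strand(other):
            raise ValueError("union_span requires same chromosome and strand")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end), self.strand
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Bases strictly between the two intervals; 0 when they touch or overlap."""
        if self.chrom != other.chrom:
            raise ValueError("gap_to requires same chromosome")
        if self.intersection_length(other) > 0:
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, mode: str = "union"
) -> float:
    """Strand-aware overlap fraction used for replicate reproducibility.

    ``mode="union"`` (default): ``|a ∩ b| / |a ∪ b|`` where the denominator is
    the length of the union of the two spans (Jaccard). ``mode="each"``:
    ``|a ∩ b| / min(|a|, |b|)`` so the 1/3 threshold applies to each cluster's
    own length. Different strands or chromosomes never overlap.
    """
    if not a.same_strand(b):
        return 0.0
    inter = a.intersection_length(b)
    if inter == 0:
        return 0.0
    if mode == "union":
        denom = a.length + b.length - inter
    elif mode == "each":
        denom = min(a.length, b.length)
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    return inter / denom
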