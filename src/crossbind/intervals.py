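"""Core genomic data model: intervals, peaks, gene models.

All coordinates are 0-based, half-open ``[start, end)``, BED-style. GTF input
is converted on read. Strand is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor of the interval midpoint."""
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge distance; 0 when overlapping, None on different chroms."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak with its tissue/stage provenance.

    ``summit`` is an offset within the interval (narrowPeak column 10);
    the representative point used for annotation is the summit when present,
    else the floor of the interval midpoint.
    """

    interval: GenomicInterval
    id: str
    tissue: str = ""
    stage: str = ""
    score: float = 0.0
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be non-negative, got {self.score}")
        if self.summit is not None and not 0 <= self.summit < len(self.interval):
            raise ValueError(
                f"summit {self.summit} outside peak of length {len(self.interval)}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def representative_point(self) -> int:
        if self.summit is not None:
            return self.interval.start + self.summit
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """Single-isoform gene model: body, strand, exons and optional UTRs.

    The TSS is the body start on '+' and ``end - 1`` on '-'; the TES is the
    opposite extremity.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for exon in self.exons:
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(f"exon {exon} outside gene body {self.interval}")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = exon.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.chrom, a.end, b.start, self.strand)
                )
        return tuple(out)

    def with_exons(self, exons: Sequence[GenomicInterval]) -> "GeneModel":
        return replace(self, exons=tuple(exons))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome.

    Returns a list sorted by (chrom, start); strand is dropped (merged
    intervals are unstranded).
    """
    by_key = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_key:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end
                )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))
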