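"""Genomic interval primitives, 0-based half-open throughout (BED convention)."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GenomicInterval", "merge_intervals", "subtract_intervals", "total_length"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")
        if self.start < 0:
            raise ValueError("start must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Union of intervals: overlapping or bookended intervals are merged."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def subtract_intervals(segment: GenomicInterval, others) -> list[GenomicInterval]:
    """Maximal sub-intervals of ``segment`` with zero base overlap with ``others``."""
    blocks = [
        o for o in merge_intervals(others)
        if o.chrom == segment.chrom and o.start < segment.end and o.end > segment.start
    ]
    out = []
    cursor = segment.start
    for b in blocks:
        if b.start > cursor:
            out.append(GenomicInterval(segment.chrom, cursor, b.start, segment.strand))
        cursor = max(cursor, b.end)
    if cursor < segment.end:
        out.append(GenomicInterval(segment.chrom, cursor, segment.end, segment.strand))
    return out


def total_length(intervals) -> int:
    return sum(iv.length for iv in intervals)
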