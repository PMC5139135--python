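"""Chromosome-anchored intervals, 0-based half-open (BED convention)."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome, 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_point(self, pos0: int) -> bool:
        """Whether a 0-based position falls in the interval."""
        return self.start <= pos0 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Smallest of the two mutual overlap fractions (0 if disjoint)."""
    inter = a.intersect(b)
    if inter is None or a.length == 0 or b.length == 0:
        return 0.0
    return min(inter.length / a.length, inter.length / b.length)
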