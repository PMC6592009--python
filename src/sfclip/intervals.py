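"""Genomic intervals and interval-set algebra.

All coordinates in sfclip are 0-based, half-open ``[start, end)`` — the BED
convention — on a single genome build. Strand is ``"+"``, ``"-"`` or ``"."``
(unknown). A strand-unknown interval is treated as matching both strands
wherever strand-aware overlap is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)`` with a strand."""

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
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        """True iff the two intervals share >= 1 nt.

        With ``stranded=True``, intervals on explicitly opposite strands
        never overlap; a ``"."`` strand matches either.
        """
        if self.chrom != other.chrom:
            return False
        if stranded and "." not in (self.strand, other.strand):
            if self.strand != other.strand:
                return False
        return self.start < other.end and other.start < self.end

    def pad(self, nt: int) -> "GenomicInterval":
        """Extend by ``nt`` on both sides, clipping at position 0."""
        return GenomicInterval(
            self.chrom, max(0, self.start - nt), self.end + nt, self.strand
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per (chrom, strand).

    Adjacent (end == next start) intervals are coalesced: a binding site
    cannot fall between them. The result is sorted and pairwise disjoint
    within each (chrom, strand) bucket. Idempotent.
    """
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    merged: list[GenomicInterval] = []
    for (chrom, strand), ivs in by_key.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e, strand))
    merged.sort()
    return merged


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    """Sum of interval lengths (meaningful for disjoint sets)."""
    return sum(len(iv) for iv in intervals)
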