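"""Genomic interval primitives shared by every analysis stage.

Coordinates are 0-based, half-open (BED convention) throughout the
package.  GTF input is converted on read.  Chromosome names are passed
through verbatim — no ``chr`` prefix normalisation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Annotation",
    "TagSet",
    "merge_intervals",
    "distance_to_nearest_tss",
    "distance_to_point",
    "window_around",
    "intervals_overlap",
    "edge_distance",
    "total_coverage",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TSS:
    """One annotated transcription start site."""

    gene_id: str
    chrom: str
    pos: int
    strand: str = "."


@dataclass
class ESTRecord:
    """A spliced-EST interval with the position of its 5' end."""

    interval: GenomicInterval
    five_prime: int

    def spans_point(self, pos: int) -> bool:
        # "spans a TSS" = the EST interval strictly contains the coordinate
        return self.interval.start < pos < self.interval.end


@dataclass
class Annotation:
    """Gene annotation bundle: TSSs, gene bodies, rRNA genes, ESTs.

    For a minus-strand gene the TSS is its annotated end coordinate.
    """

    tss_list: list[TSS] = field(default_factory=list)
    gene_bodies: list[GenomicInterval] = field(default_factory=list)
    rrna_genes: list[GenomicInterval] = field(default_factory=list)
    est_records: list[ESTRecord] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def tss_positions(self, chrom: str) -> np.ndarray:
        """Sorted TSS coordinates on one chromosome."""
        pos = sorted(t.pos for t in self.tss_list if t.chrom == chrom)
        return np.asarray(pos, dtype=np.int64)


class TagSet:
    """Stranded RNA tag (read 5'-end) positions plus the library size.

    ``total_tags`` is the library total N, which may exceed the number of
    stored positions (tags on unrepresented chromosomes, for instance).
    """

    def __init__(
        self,
        positions: dict[str, np.ndarray] | dict[str, Sequence[int]],
        strands: dict[str, np.ndarray] | None = None,
        total_tags: int | None = None,
    ):
        self.positions: dict[str, np.ndarray] = {}
        self.strands: dict[str, np.ndarray] = {}
        n_stored = 0
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            order = np.argsort(arr, kind="stable")
            self.positions[chrom] = arr[order]
            if strands is not None and chrom in strands:
                s = np.asarray(strands[chrom])
                self.strands[chrom] = s[order]
            else:
                self.strands[chrom] = np.full(len(arr), ".", dtype="<U1")
            n_stored += len(arr)
        if total_tags is None:
            total_tags = n_stored
        if total_tags < n_stored:
            raise ValueError("total_tags < number of stored positions")
        self.total_tags = int(total_tags)

    def count_in(self, chrom: str, start: int, end: int, strand: str | None = None) -> int:
        """Number of tags with position in half-open ``[start, end)``."""
        if chrom not in self.positions:
            return 0
        pos = self.positions[chrom]
        lo, hi = np.searchsorted(pos, [start, end], side="left")
        if strand is None:
            return int(hi - lo)
        return int(np.sum(self.strands[chrom][lo:hi] == strand))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping intervals into disjoint sorted spans.

    Intervals that merely touch (``a.end == b.start``) are *not* merged:
    the half-open convention means they share no base.  Strand is dropped
    (merged spans are unstranded).  Empty input gives empty output.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def total_coverage(intervals: Iterable[GenomicInterval]) -> int:
    """Total number of distinct bases covered by the intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))


def distance_to_point(iv: GenomicInterval, pos: int) -> int:
    """Distance from an interval to a point: 0 if inside, else edge gap."""
    if iv.contains_point(pos):
        return 0
    if pos < iv.start:
        return iv.start - pos
    return pos - (iv.end - 1)


class NoReferenceTSSError(ValueError):
    """Raised when a chromosome has no annotated TSS to measure against."""


def distance_to_nearest_tss(iv: GenomicInterval, ann: Annotation) -> int:
    """Minimum distance (bp) from ``iv`` to any annotated TSS.

    Zero when a TSS falls inside the interval.  Raises
    :class:`NoReferenceTSSError` when the chromosome has no TSS.
    """
    pos = ann.tss_positions(iv.chrom)
    if len(pos) == 0:
        raise NoReferenceTSSError(f"no TSS annotated on {iv.chrom}")
    # inside?
    lo, hi = np.searchsorted(pos, [iv.start, iv.end], side="left")
    if hi > lo:
        return 0
    best = np.inf
    if lo > 0:
        best = min(best, iv.start - pos[lo - 1])
    if lo < len(pos):
        best = min(best, pos[lo] - (iv.end - 1))
    return int(best)


def window_around(center: int, half_width: int, chrom_len: int, chrom: str = ".") -> GenomicInterval:
    """Half-open window of ±``half_width`` around ``center``, clipped to the chromosome."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if not (0 <= center < chrom_len):
        raise ValueError(f"center {center} outside chromosome of length {chrom_len}")
    return GenomicInterval(chrom, max(0, center - half_width), min(chrom_len, center + half_width))


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.overlaps(b)


def edge_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Edge-to-edge gap between two intervals on one chromosome (0 if they overlap)."""
    if a.chrom != b.chrom:
        raise ValueError("intervals on different chromosomes")
    if a.overlaps(b):
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end
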