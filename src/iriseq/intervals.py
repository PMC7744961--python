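"""Half-open genomic interval primitives and sorted-interval-list algebra.

All coordinates are 0-based half-open ``[start, end)`` (BED convention).
Interval lists are plain lists of ``(start, end)`` tuples; the algebra
functions accept unsorted, possibly overlapping input and return sorted,
merged (disjoint, non-adjacent) output. These primitives underlie the
shared-region reduction of multi-isoform gene models, so they are kept
explicit and independently testable against per-base oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Iterable, NamedTuple, Sequence


class GenomicInterval(NamedTuple):
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def validate(self) -> "GenomicInterval":
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        return self

    @property
    def length(self) -> int:
        return self.end - self.start


IntervalPair = tuple[int, int]


def merge_intervals(intervals: Iterable[IntervalPair]) -> list[IntervalPair]:
    """Sort and merge overlapping or book-ended intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[IntervalPair] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def intersect_intervals(
    a: Sequence[IntervalPair], b: Sequence[IntervalPair]
) -> list[IntervalPair]:
    """Intersection of two merged interval lists (linear sweep)."""
    out: list[IntervalPair] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(lists: Sequence[Sequence[IntervalPair]]) -> list[IntervalPair]:
    if not lists:
        return []
    return list(reduce(intersect_intervals, lists))


def subtract_intervals(
    a: Sequence[IntervalPair], b: Sequence[IntervalPair]
) -> list[IntervalPair]:
    """Set difference a \\ b for merged interval lists."""
    out: list[IntervalPair] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(intervals: Iterable[IntervalPair]) -> int:
    return sum(e - s for s, e in intervals)


@dataclass
class GeneModel:
    """A gene's isoforms as exon interval lists on one chromosome/strand.

    ``transcripts`` maps transcript id -> sorted, merged exon list.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[IntervalPair]]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        for tx, exons in self.transcripts.items():
            if not exons:
                raise ValueError(f"gene {self.gene_id}, transcript {tx}: no exons")

    @property
    def span(self) -> IntervalPair:
        return (
            min(ex[0][0] for ex in self.transcripts.values()),
            max(ex[-1][1] for ex in self.transcripts.values()),
        )


@dataclass
class SharedRegions:
    """Regions exonic (intronic) in every annotated isoform of a gene."""

    gene_id: str
    chrom: str
    strand: str
    shared_exonic: list[IntervalPair]
    shared_intronic: list[IntervalPair]


@dataclass
class IntronRecord:
    """One shared intronic segment with its flanking shared exonic segments.

    ``index`` counts in transcription order (1-based); on the minus strand the
    leftmost intron therefore has the highest index.
    """

    intron_id: str
    gene_id: str
    interval: GenomicInterval
    flank_up: GenomicInterval
    flank_down: GenomicInterval
    index: int
    length: int
    gc_content: float | None = None

    def __post_init__(self) -> None:
        if not (
            self.flank_up.end <= self.interval.start
            and self.interval.end <= self.flank_down.start
        ):
            raise ValueError(
                f"{self.intron_id}: flanks must bracket the intron on the "
                "forward coordinate axis"
            )
        if self.length != self.interval.length:
            raise ValueError(f"{self.intron_id}: length != end - start")
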