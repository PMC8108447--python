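"""Strand-blind interval algebra for annotation intersections.

Every intersection the pipeline performs (transcript x pseudogene,
x retrocopy track, x CAGE peaks) reduces to the operations here. Overlap
is measured in exonic base pairs and ignores strand; orientation is a
separate classification step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genomic_io import GeneModel, GenomicInterval, TranscriptModel

INF = math.inf


@dataclass
class IntervalSet:
    """A normalised (sorted, merged) set of intervals on one chromosome."""

    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        chroms = {iv.chrom for iv in self.intervals}
        if len(chroms) > 1:
            raise ValueError("IntervalSet spans multiple chromosomes")
        self.intervals = merge(self.intervals)

    @property
    def chrom(self) -> str | None:
        return self.intervals[0].chrom if self.intervals else None

    def __len__(self) -> int:
        return len(self.intervals)


def merge(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or book-ended intervals. Idempotent."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda i: (i.start, i.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 across chromosomes. Strand-blind."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def exonic_overlap_bp(tx: TranscriptModel, feature: IntervalSet) -> int:
    """Total exonic bases of ``tx`` covered by the merged feature set.

    Each base counts once because both the exon chain and the feature set
    are non-overlapping after normalisation.
    """
    if feature.chrom is None or feature.chrom != tx.chrom:
        return 0
    total = 0
    for e in tx.exons:
        for iv in feature.intervals:
            if iv.start >= e.end:
                break
            total += overlap_bp(e, iv)
    return total


def is_intronic(tx: TranscriptModel, gene: GeneModel) -> bool:
    """True iff ``tx`` lies inside the gene's span but touches none of its exons."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.id} has no transcripts")
    span = gene.span
    if tx.chrom != span.chrom:
        return False
    if tx.start < span.start or tx.end > span.end:
        return False
    exon_set = IntervalSet(gene.exon_intervals())
    return exonic_overlap_bp(tx, exon_set) == 0


def nearest_distance(point: int, ivset: IntervalSet) -> float:
    """Distance from a point to the nearest interval; 0 inside, ``inf`` if empty.

    Outside an interval the distance is the gap to the closest covered base
    (the base at ``start`` or ``end - 1``).
    """
    if not ivset.intervals:
        return INF
    best = INF
    for iv in ivset.intervals:
        if iv.start <= point < iv.end:
            return 0
        if point < iv.start:
            best = min(best, iv.start - point)
        else:
            best = min(best, point - (iv.end - 1))
    return best
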