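"""Per-transcript evidence features: CAGE TSS support and polyA-signal scanning.

A transcript's 5' end is supported when it falls within a configurable
window (default 100 bp, boundary inclusive) of a CAGE peak. The 3' end is
scanned for the canonical polyadenylation hexamers AATAAA and ATTAAA in a
genomic window ending at the transcript's terminal base, read in
transcript orientation; the canonical signal normally sits 10-40 nt
upstream of the cleavage site, so the window looks upstream by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .genomic_io import TranscriptModel
from .intervals import IntervalSet, nearest_distance

log = logging.getLogger(__name__)


@dataclass
class TssSupport:
    tss: int
    distance_to_peak: float
    supported: bool


class PolyAMotif(str, Enum):
    AATAAA = "AATAAA"
    ATTAAA = "ATTAAA"
    none = "none"


@dataclass
class PolyACall:
    motif: PolyAMotif
    offset_from_3prime: int | None = None  # 0 = motif's last base is the terminal base


def transcript_tss(tx: TranscriptModel) -> int:
    """0-based coordinate of the first transcribed base (strand-aware 5' end)."""
    if tx.strand == "+":
        return tx.exons[0].start
    return tx.exons[-1].end - 1


def cage_support(tss: int, peaks: IntervalSet, window: int = 100) -> TssSupport:
    """Distance from a TSS to the nearest CAGE peak; supported iff <= window."""
    if window < 0:
        raise ValueError("window must be >= 0")
    d = nearest_distance(tss, peaks)
    return TssSupport(tss=tss, distance_to_peak=d, supported=d <= window)


def cage_metaprofile(
    tss_list: Sequence[tuple[int, str]],
    signal: Mapping[int, float] | Mapping[str, Mapping[int, float]],
    flank: int = 500,
    bin: int = 10,
    chroms: Sequence[str] | None = None,
) -> np.ndarray:
    """Mean per-base CAGE signal in bins around a cohort of TSSs, 5'->3'.

    ``tss_list`` holds (position, strand) pairs, or (chrom, position,
    strand) triples when ``signal`` is keyed by chromosome. Windows of
    ``[tss - flank, tss + flank)`` are reversed for '-' strand transcripts
    so the profile reads 5'->3'; missing signal counts as 0 and the
    per-bin value is the per-base mean averaged across TSSs.
    """
    if (2 * flank) % bin != 0:
        raise ValueError("bin must divide 2*flank")
    nbins = (2 * flank) // bin
    acc = np.zeros(nbins)
    n = 0
    for item in tss_list:
        if len(item) == 3:
            chrom, tss, strand = item
            sig = signal.get(chrom, {})
        else:
            tss, strand = item
            sig = signal
        win = np.array([sig.get(p, 0.0) for p in range(tss - flank, tss + flank)])
        if strand == "-":
            win = win[::-1]
        acc += win.reshape(nbins, bin).mean(axis=1)
        n += 1
    return acc / n if n else acc


def _three_prime_window(
    tx: TranscriptModel, genome: Mapping[str, str], window: int
) -> str:
    """Genomic (unspliced) window of ``window`` bases ending at and
    including the 3'-terminal base, read in transcript orientation."""
    chrom_seq = genome[tx.chrom]
    if tx.strand == "+":
        end = tx.end  # terminal base at end - 1
        start = end - window
        if start < 0:
            log.warning("polyA window clipped at chromosome start for %s", tx.id)
            start = 0
        return chrom_seq[start:end]
    start = tx.start  # terminal base (transcript orientation) at start
    stop = start + window
    if stop > len(chrom_seq):
        log.warning("polyA window clipped at chromosome end for %s", tx.id)
        stop = len(chrom_seq)
    return str(Seq(chrom_seq[start:stop]).reverse_complement())


def polya_scan(
    tx: TranscriptModel, genome: Mapping[str, str], window: int = 100
) -> PolyACall:
    """Scan the 3'-terminal genomic window for AATAAA/ATTAAA.

    AATAAA takes precedence when both motifs occur; within a motif the
    occurrence closest to the 3' end is reported. The offset counts bases
    from the terminal base back to the motif's last base (0 = motif ends
    on the terminal base).
    """
    if window < 6:
        raise ValueError("window must be >= 6")
    win = _three_prime_window(tx, genome, window)
    for motif in (PolyAMotif.AATAAA, PolyAMotif.ATTAAA):
        pos = win.rfind(motif.value)
        if pos >= 0:
            offset = len(win) - (pos + 6)
            return PolyACall(motif=motif, offset_from_3prime=offset)
    return PolyACall(motif=PolyAMotif.none)


def transcript_features(
    tx: TranscriptModel,
    genome: Mapping[str, str],
    peaks: IntervalSet,
    cage_window: int = 100,
    polya_window: int = 100,
) -> tuple[TssSupport, PolyACall]:
    """Convenience: CAGE support and polyA call for one transcript."""
    tss = transcript_tss(tx)
    return (
        cage_support(tss, peaks, window=cage_window),
        polya_scan(tx, genome, window=polya_window),
    )
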