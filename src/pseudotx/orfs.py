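"""ORF discovery, parent-ORF fraction, and gene-pseudogene fusion accounting.

An ORF here is the longest ATG-initiated, stop-terminated reading frame on
the transcript strand; open-ended 3' frames are not called. A fusion is a
transcript assigned to a protein-coding host gene whose ORF draws codons
from a pseudogene retrocopy interval; a codon counts as pseudogene-derived
when at least two of its three bases map inside the retrocopy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genomic_io import Biotype, GeneModel, PseudogeneRecord, TranscriptModel
from .intervals import IntervalSet, exonic_overlap_bp

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_STANDARD.stop_codons)


class RelativeStrand(str, Enum):
    sense = "sense"
    antisense = "antisense"


@dataclass
class OrfRecord:
    start_nt: int  # 0-based offset in the transcript sequence
    end_nt: int    # exclusive; includes the stop codon
    aa_length: int  # excludes the stop
    protein: str
    frame: int


@dataclass
class FusionRecord:
    tx_id: str
    host_gene_id: str
    pseudogene_id: str
    codons_from_pseudogene: int
    pseudogene_strand_relative: RelativeStrand


def translate(cdna: str) -> str:
    """Translate a cDNA whose length is divisible by 3; stops render '*',
    codons with non-ACGT bases render 'X'."""
    if len(cdna) % 3 != 0:
        raise ValueError(f"sequence length {len(cdna)} not divisible by 3")
    cdna = cdna.upper()
    out = []
    for i in range(0, len(cdna), 3):
        codon = cdna[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def find_longest_orf(tx_sequence: str) -> OrfRecord | None:
    """Longest ATG...stop ORF over frames 0-2 of the given strand.

    The stop codon is required and included in ``[start_nt, end_nt)``;
    ties go to the smallest start.
    """
    seq = tx_sequence.upper()
    best: OrfRecord | None = None
    for frame in range(3):
        i = frame
        open_start: int | None = None
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in STOP_CODONS:
                aa_len = (i - open_start) // 3
                if best is None or aa_len > best.aa_length or (
                    aa_len == best.aa_length and open_start < best.start_nt
                ):
                    cds = seq[open_start : i + 3]
                    best = OrfRecord(
                        start_nt=open_start,
                        end_nt=i + 3,
                        aa_length=aa_len,
                        protein=translate(cds[:-3]),
                        frame=frame,
                    )
                open_start = None
                # allow a later ATG in this frame after the stop
            i += 3
        # re-scan frame for ATGs that were skipped while an ORF was open:
        # nested ATGs start shorter ORFs ending at the same stop, so the
        # longest-ORF answer is unaffected.
    return best


def orf_at(tx_sequence: str, start_nt: int) -> OrfRecord | None:
    """ORF starting at a given ATG offset, ending at the first in-frame stop.

    Returns None when ``start_nt`` is not an ATG or no stop follows;
    useful for measuring disruption of an annotated start without
    downstream re-initiation.
    """
    seq = tx_sequence.upper()
    if seq[start_nt : start_nt + 3] != "ATG":
        return None
    i = start_nt + 3
    while i + 3 <= len(seq):
        if seq[i : i + 3] in STOP_CODONS:
            cds = seq[start_nt : i + 3]
            return OrfRecord(
                start_nt=start_nt,
                end_nt=i + 3,
                aa_length=(i - start_nt) // 3,
                protein=translate(cds[:-3]),
                frame=start_nt % 3,
            )
        i += 3
    return None


def orf_exceeds(orf: OrfRecord | None, threshold_aa: int = 100) -> bool:
    """Strictly longer than the amino-acid threshold ('> 100 aa' semantics)."""
    return orf is not None and orf.aa_length > threshold_aa


def parent_orf_fraction(pseudo_orf: OrfRecord | None, parent_orf_aa: int) -> float:
    """Pseudogene ORF length as a fraction of the parent ORF, capped at 1."""
    if parent_orf_aa < 1:
        raise ValueError("parent_orf_aa must be >= 1")
    if pseudo_orf is None:
        return 0.0
    return min(1.0, pseudo_orf.aa_length / parent_orf_aa)


def parent_orf_aa_from_cds(gene: GeneModel) -> int:
    """Parent ORF length in aa from annotated CDS intervals (stop excluded)."""
    total = sum(len(c) for c in gene.cds)
    return max(0, total // 3 - 1)


def codon_genomic_positions(tx: TranscriptModel, orf: OrfRecord) -> list[tuple[int, int, int]]:
    """Map each ORF codon to the genomic positions of its three bases.

    Transcript offsets are walked through the exon chain; for '-' strand
    transcripts offset 0 is the last genomic base of the last exon.
    """
    positions: list[int] = []
    if tx.strand == "+":
        for e in tx.exons:
            positions.extend(range(e.start, e.end))
    else:
        for e in reversed(tx.exons):
            positions.extend(range(e.end - 1, e.start - 1, -1))
    codons = []
    for c in range(orf.start_nt, orf.end_nt - 3, 3):  # exclude stop codon
        codons.append((positions[c], positions[c + 1], positions[c + 2]))
    return codons


def detect_fusions(
    classified: list,
    genes: list[GeneModel],
    pseudogene_records: Mapping[str, PseudogeneRecord],
    genome: Mapping[str, str],
) -> list[FusionRecord]:
    """Find transcripts of protein-coding genes whose ORFs draw codons from
    a pseudogene retrocopy; count codons by the 2-of-3 base majority rule."""
    if not genome:
        raise ValueError("genome sequence required for fusion detection")
    by_id = {g.id: g for g in genes}
    out: list[FusionRecord] = []
    for ct in classified:
        host = by_id.get(ct.assigned_gene_id)
        if host is None or host.biotype is not Biotype.protein_coding:
            continue
        tx = ct.tx
        for pid, rec in pseudogene_records.items():
            ri = rec.retro_interval
            if exonic_overlap_bp(tx, IntervalSet([ri])) < 1:
                continue
            seq = tx.sequence or tx.spliced_sequence(genome)
            orf = find_longest_orf(seq)
            if orf is None:
                continue
            n = 0
            for bases in codon_genomic_positions(tx, orf):
                inside = sum(1 for p in bases if ri.start <= p < ri.end)
                if inside >= 2:
                    n += 1
            if n >= 1:
                rel = (
                    RelativeStrand.sense
                    if tx.strand == rec.strand
                    else RelativeStrand.antisense
                )
                out.append(
                    FusionRecord(
                        tx_id=tx.id,
                        host_gene_id=host.id,
                        pseudogene_id=pid,
                        codons_from_pseudogene=n,
                        pseudogene_strand_relative=rel,
                    )
                )
    return out
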