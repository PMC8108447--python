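"""Pseudogene-transcript classification.

The central inference of the pipeline: decide which long-read transcript
models are pseudogene transcripts, whether they are *independent* of known
genes (non-intronic and with greater exonic overlap with the pseudogene
than with any other gene model), and their orientation (sense/antisense)
relative to the pseudogene, whose annotated strand encodes the parent-mRNA
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .genomic_io import Biotype, GeneModel, PseudogeneRecord, TranscriptModel
from .intervals import IntervalSet, exonic_overlap_bp, is_intronic

PSEUDOGENE_BIOTYPES = {Biotype.processed_pseudogene, Biotype.unprocessed_pseudogene}


class Independence(str, Enum):
    independent = "independent"
    dependent = "dependent"


class Orientation(str, Enum):
    sense = "sense"
    antisense = "antisense"


@dataclass
class ClassifiedTranscript:
    tx: TranscriptModel
    assigned_gene_id: str
    assignment_overlap_bp: int
    is_pseudogene_transcript: bool
    retrocopy_confirmed: bool = False
    independence: Independence | None = None
    orientation: Orientation | None = None
    multi_exonic: bool = False
    shares_reference_junction: bool = False
    shared_junction_count: int = 0


def filter_by_support(txs: list[TranscriptModel], min_fl: int = 2) -> list[TranscriptModel]:
    """Keep transcripts supported by at least ``min_fl`` full-length reads."""
    return [t for t in txs if t.fl_read_count >= min_fl]


def assign_transcript(tx: TranscriptModel, genes: list[GeneModel]) -> tuple[str, int]:
    """Assign a transcript to the gene model with maximal exonic-bp overlap.

    Ties are broken by preferring pseudogene biotypes, then by the
    lexicographically smallest gene id. Returns ``("none", 0)`` when no
    gene overlaps.
    """
    best: tuple[int, int, str] | None = None  # (overlap, pseudo-pref, id)
    best_gene: str = "none"
    best_ov = 0
    for g in genes:
        if not g.transcripts or g.chrom != tx.chrom:
            continue
        ov = exonic_overlap_bp(tx, IntervalSet(g.exon_intervals()))
        if ov == 0:
            continue
        is_pseudo = g.biotype in PSEUDOGENE_BIOTYPES
        key = (ov, 1 if is_pseudo else 0)
        if best is None or key > best[:2] or (key == best[:2] and g.id < best[2]):
            best = (*key, g.id)
            best_gene, best_ov = g.id, ov
    return best_gene, best_ov


def confirm_retrocopy(tx: TranscriptModel, retro_track: IntervalSet) -> bool:
    """True iff the transcript's exons directly touch a retrocopy interval."""
    return exonic_overlap_bp(tx, retro_track) >= 1


def classify_independence(
    tx: TranscriptModel,
    assigned: PseudogeneRecord,
    other_genes: list[GeneModel],
) -> Independence:
    """Independent iff the pseudogene wins every overlap comparison strictly
    and the transcript is not intronic within any non-pseudogene gene."""
    pseudo_ov = exonic_overlap_bp(tx, IntervalSet(assigned.gene.exon_intervals()))
    for g in other_genes:
        if g.biotype in PSEUDOGENE_BIOTYPES or not g.transcripts:
            continue
        if g.chrom != tx.chrom:
            continue
        ov = exonic_overlap_bp(tx, IntervalSet(g.exon_intervals()))
        if ov >= pseudo_ov:
            return Independence.dependent
        if is_intronic(tx, g):
            return Independence.dependent
    return Independence.independent


def classify_orientation(tx: TranscriptModel, pseudogene: PseudogeneRecord) -> Orientation:
    """Sense iff the transcript runs with the pseudogene's (parent-mRNA) strand."""
    if pseudogene.strand not in ("+", "-"):
        raise ValueError(f"pseudogene {pseudogene.gene.id}: orientation undefined for strand '.'")
    return Orientation.sense if tx.strand == pseudogene.strand else Orientation.antisense


def _junctions(tx: TranscriptModel) -> set[tuple[str, int, int, str]]:
    return {
        (tx.chrom, a.end, b.start, tx.strand)
        for a, b in zip(tx.exons, tx.exons[1:])
    }


def shared_junctions(
    tx: TranscriptModel, reference_txs: list[TranscriptModel]
) -> tuple[bool, int]:
    """Count tx splice junctions exactly matching any reference junction.

    A junction is the (chrom, donor end, acceptor start, strand) tuple of a
    consecutive exon pair; mono-exonic transcripts share nothing.
    """
    own = _junctions(tx)
    if not own:
        return False, 0
    ref: set[tuple[str, int, int, str]] = set()
    for r in reference_txs:
        ref |= _junctions(r)
    n = len(own & ref)
    return n >= 1, n


def classify_cohort(
    txs: list[TranscriptModel],
    genes: list[GeneModel],
    pseudogenes: dict[str, PseudogeneRecord],
    retro_track: IntervalSet | dict[str, IntervalSet],
    min_fl: int = 2,
) -> list[ClassifiedTranscript]:
    """Run the full per-transcript classification over a cohort.

    ``retro_track`` may be a single set or a per-chromosome mapping.
    Unprocessed pseudogenes flow through orientation but skip retrocopy
    confirmation (a retrocopy interval only exists for processed copies).
    """
    reference_txs = [t for g in genes for t in g.transcripts]
    by_id = {g.id: g for g in genes}
    out: list[ClassifiedTranscript] = []
    for tx in filter_by_support(txs, min_fl=min_fl):
        gene_id, ov = assign_transcript(tx, genes)
        gene = by_id.get(gene_id)
        is_pseudo_tx = gene is not None and gene.biotype in PSEUDOGENE_BIOTYPES
        ct = ClassifiedTranscript(
            tx=tx,
            assigned_gene_id=gene_id,
            assignment_overlap_bp=ov,
            is_pseudogene_transcript=is_pseudo_tx,
        )
        ct.multi_exonic = len(tx.exons) > 1
        ct.shares_reference_junction, ct.shared_junction_count = shared_junctions(
            tx, reference_txs
        )
        if is_pseudo_tx and gene_id in pseudogenes:
            rec = pseudogenes[gene_id]
            if isinstance(retro_track, dict):
                track = retro_track.get(tx.chrom, IntervalSet([]))
            else:
                track = retro_track
            if gene.biotype is Biotype.processed_pseudogene:
                ct.retrocopy_confirmed = confirm_retrocopy(tx, track)
            others = [g for g in genes if g.id != gene_id]
            ct.independence = classify_independence(tx, rec, others)
            ct.orientation = classify_orientation(tx, rec)
        out.append(ct)
    return out
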