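"""End-to-end orchestration: files (or a Simulation) in, annotated cohort out.

Chains classification, TSS/polyA feature scoring, ORF analysis, fusion
detection and the dN/dS pipeline, and derives a single per-transcript
label from the same vocabulary the simulator's truth manifest uses, so
planted-truth recovery can be scored directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .classifier import (
    ClassifiedTranscript,
    Independence,
    Orientation,
    classify_cohort,
)
from .conservation import DnDsEstimate, pairwise_dnds
from .features import PolyACall, TssSupport, transcript_features, transcript_tss
from .genomic_io import (
    Biotype,
    GeneModel,
    PseudogeneRecord,
    TranscriptModel,
    read_abundance,
    read_bed,
    read_fasta,
    read_gtf,
)
from .intervals import IntervalSet
from .orfs import (
    FusionRecord,
    OrfRecord,
    detect_fusions,
    find_longest_orf,
    parent_orf_aa_from_cds,
    parent_orf_fraction,
)
from .report import SummaryReport, summarize


@dataclass
class CohortResult:
    classified: list[ClassifiedTranscript]
    features: dict[str, tuple[TssSupport, PolyACall]]
    orfs: dict[str, tuple[OrfRecord | None, float]]
    fusions: list[FusionRecord]
    dnds: dict[str, tuple[DnDsEstimate | None, str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    report: SummaryReport | None = None


def derive_labels(
    classified: Sequence[ClassifiedTranscript], fusions: Sequence[FusionRecord]
) -> dict[str, str]:
    """One label per transcript: fusion, parent_mRNA, dependent_intronic,
    independent_sense or independent_antisense."""
    fusion_ids = {f.tx_id for f in fusions}
    labels: dict[str, str] = {}
    for c in classified:
        if c.tx.id in fusion_ids:
            labels[c.tx.id] = "fusion"
        elif not c.is_pseudogene_transcript:
            labels[c.tx.id] = "parent_mRNA"
        elif c.independence is Independence.dependent:
            labels[c.tx.id] = "dependent_intronic"
        elif c.orientation is Orientation.antisense:
            labels[c.tx.id] = "independent_antisense"
        else:
            labels[c.tx.id] = "independent_sense"
    return labels


def run_cohort(
    txs: list[TranscriptModel],
    genes: list[GeneModel],
    pseudogene_records: Mapping[str, PseudogeneRecord],
    genome: Mapping[str, str],
    cage_peaks: Sequence,
    cdnas: Mapping[str, str] | None = None,
    ortholog_windows: Mapping[str, str] | None = None,
    min_fl: int = 2,
    cage_window: int = 100,
    polya_window: int = 100,
) -> CohortResult:
    retro_by_chrom: dict[str, list] = {}
    for rec in pseudogene_records.values():
        retro_by_chrom.setdefault(rec.retro_interval.chrom, []).append(rec.retro_interval)
    retro_track = {c: IntervalSet(ivs) for c, ivs in retro_by_chrom.items()}

    classified = classify_cohort(
        txs, genes, dict(pseudogene_records), retro_track, min_fl=min_fl
    )

    peaks_by_chrom: dict[str, list] = {}
    for p in cage_peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    peak_sets = {c: IntervalSet(ivs) for c, ivs in peaks_by_chrom.items()}

    genes_by_id = {g.id: g for g in genes}
    features: dict[str, tuple[TssSupport, PolyACall]] = {}
    orf_out: dict[str, tuple[OrfRecord | None, float]] = {}
    for c in classified:
        peaks = peak_sets.get(c.tx.chrom, IntervalSet([]))
        features[c.tx.id] = transcript_features(
            c.tx, genome, peaks, cage_window=cage_window, polya_window=polya_window
        )
        if c.is_pseudogene_transcript:
            orf = find_longest_orf(c.tx.spliced_sequence(genome))
            frac = 0.0
            rec = pseudogene_records.get(c.assigned_gene_id)
            if rec is not None:
                parent = genes_by_id.get(rec.parent_gene_id)
                if parent is not None and parent.cds:
                    frac = parent_orf_fraction(orf, parent_orf_aa_from_cds(parent))
            orf_out[c.tx.id] = (orf, frac)

    fusions = detect_fusions(classified, genes, dict(pseudogene_records), genome)

    dnds: dict[str, tuple[DnDsEstimate | None, str]] = {}
    if cdnas and ortholog_windows:
        for pid, cdna in cdnas.items():
            window = ortholog_windows.get(pid)
            if window is None:
                continue
            dnds[pid] = pairwise_dnds(cdna, window)

    result = CohortResult(
        classified=classified,
        features=features,
        orfs=orf_out,
        fusions=fusions,
        dnds=dnds,
    )
    result.labels = derive_labels(classified, fusions)
    result.report = summarize(
        classified,
        features={k: v for k, v in features.items()},
        orfs=orf_out,
        dnds=[e for e, _ in dnds.values() if e is not None],
    )
    return result


def run_from_files(
    transcripts_path: str | Path,
    annotation_path: str | Path,
    retro_path: str | Path,
    genome_path: str | Path,
    abundance_path: str | Path | None = None,
    cage_peaks_path: str | Path | None = None,
    cdna_path: str | Path | None = None,
    windows_path: str | Path | None = None,
    parents_path: str | Path | None = None,
    min_fl: int = 2,
) -> CohortResult:
    """Load the standard-format inputs and run the full cohort analysis.

    The retrocopy BED supplies both the confirmation track and, matched
    by name against pseudogene gene ids, the parent linkage via the
    annotation (a pseudogene record is created for every pseudogene gene
    whose id appears in the BED; parent ids are taken as the BED score
    column is ignored).
    """
    txs = read_bed(transcripts_path, blocked=True)
    genes = read_gtf(annotation_path)
    genome = read_fasta(genome_path)
    if abundance_path is not None:
        counts = read_abundance(abundance_path)
        for t in txs:
            t.fl_read_count = counts.get(t.id, t.fl_read_count)
    import pandas as pd

    bed = pd.read_csv(
        retro_path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    from .genomic_io import GenomicInterval

    retro_by_name = {
        str(r.name): GenomicInterval(r.chrom, int(r.start), int(r.end), str(r.strand))
        for r in bed.itertuples(index=False)
    }
    parent_map: dict[str, str] = {}
    if parents_path is not None:
        pm = pd.read_csv(parents_path, sep="\t")
        parent_map = dict(zip(pm.iloc[:, 0].astype(str), pm.iloc[:, 1].astype(str)))
    records: dict[str, PseudogeneRecord] = {}
    for g in genes:
        if g.biotype is Biotype.processed_pseudogene and g.id in retro_by_name:
            records[g.id] = PseudogeneRecord(
                gene=g,
                parent_gene_id=parent_map.get(g.id, ""),
                retro_interval=retro_by_name[g.id],
            )
    peaks = read_bed(cage_peaks_path) if cage_peaks_path else []
    cdnas = read_fasta(cdna_path) if cdna_path else None
    windows = read_fasta(windows_path) if windows_path else None
    return run_cohort(
        txs, genes, records, genome, peaks,
        cdnas=cdnas, ortholog_windows=windows, min_fl=min_fl,
    )
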