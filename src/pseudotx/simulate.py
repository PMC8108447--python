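"""Synthetic genome / retrotransposition simulator with a truth manifest.

Generates a small genome containing multi-exon protein-coding parent
genes, processed pseudogenes created by copying each parent's spliced
mRNA (plus a poly-A tract) back into intergenic or intronic loci with
tunable divergence, indels and planted frameshifts, and a cohort of
transcript models over those loci: sense and antisense pseudogene
transcripts (some with a novel 5' exon from an upstream promoter),
dependent intronic transcripts, parent mRNAs, and gene-pseudogene fusion
transcripts. CAGE peaks are planted at every transcript TSS with
configurable jitter, and canonical polyA motifs are implanted upstream of
3' ends at recorded offsets. Every emitted transcript carries exactly one
truth label, so the whole pipeline is testable offline.

The simulator is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .conservation import simulate_codon_divergence
from .genomic_io import (
    Biotype,
    GeneModel,
    GenomicInterval,
    PseudogeneRecord,
    TranscriptModel,
    write_bed6,
    write_bed12,
    write_bedgraph,
    write_fasta,
    write_gtf,
    write_tsv_report,
)
from .orfs import STOP_CODONS, find_longest_orf, codon_genomic_positions

CHROM = "chr1"
_MOTIFS = ("AATAAA", "ATTAAA")
_SAFE_HEXAMER = "CAGCTG"  # motif-free replacement used when sanitising windows


@dataclass
class SimulationConfig:
    seed: int = 1
    n_parent_genes: int = 60
    exons_per_gene: tuple[int, int] = (2, 4)
    cds_length_codons: tuple[int, int] = (80, 200)
    n_pseudogenes: int = 50
    divergence: float = 0.0
    indel_rate: float = 0.0
    frameshift_fraction: float = 0.3
    antisense_fraction: float = 0.35
    intronic_insertion_fraction: float = 0.15
    fusion_count: int = 3
    cage_jitter_sd: float = 0.0
    fl_count_distribution: dict = field(
        default_factory=lambda: {"geometric_p": 0.45, "min": 1}
    )
    polya_motif_offset: tuple[int, int] = (10, 40)
    # study-condition extras (see docs/methods.md)
    novel_five_prime_exon_fraction: float = 0.5
    utr_length: int = 120
    intron_length: tuple[int, int] = (200, 800)
    cage_peak_width: int = 20
    cage_background_peaks: int = 20
    cage_depth: float = 5.0
    ortholog_t: float = 0.08
    ortholog_omega: float = 0.45

    def validate(self) -> None:
        for name in (
            "divergence", "indel_rate", "frameshift_fraction",
            "antisense_fraction", "intronic_insertion_fraction",
            "novel_five_prime_exon_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("exons_per_gene", "cds_length_codons", "intron_length", "polya_motif_offset"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty range for {name}")
        if not (10 <= self.polya_motif_offset[0] and self.polya_motif_offset[1] <= 40):
            raise ValueError("polya_motif_offset must lie within [10, 40]")


@dataclass
class PseudogeneTruth:
    pseudogene_id: str
    parent_id: str
    locus: GenomicInterval
    strand: str
    divergence: float
    frameshift: bool
    frameshift_cds_fraction: float | None
    placement: str  # intergenic | intronic
    host_gene_id: str | None
    parent_orf_aa: int
    is_fusion_source: bool = False


@dataclass
class TranscriptTruth:
    tx_id: str
    label: str  # independent_sense | independent_antisense | dependent_intronic | fusion | parent_mRNA
    tss: int
    strand: str
    fl_read_count: int
    pseudogene_id: str | None = None
    polya_motif: str | None = None
    polya_offset: int | None = None
    host_gene_id: str | None = None
    fusion_codons: int | None = None


@dataclass
class TruthManifest:
    pseudogenes: list[PseudogeneTruth] = field(default_factory=list)
    transcripts: list[TranscriptTruth] = field(default_factory=list)

    def by_tx(self) -> dict[str, TranscriptTruth]:
        return {t.tx_id: t for t in self.transcripts}


@dataclass
class Simulation:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    pseudogene_records: dict[str, PseudogeneRecord]
    transcripts: list[TranscriptModel]
    abundance: dict[str, int]
    cage_peaks: list[GenomicInterval]
    cage_signal: dict[str, dict[int, float]]
    cdnas: dict[str, str]
    ortholog_windows: dict[str, str]
    truth: TruthManifest


# ---------------------------------------------------------------------------
# sequence helpers

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return "".join(rng.choice(_BASES, size=n, p=[p_at, p_gc, p_gc, p_at]))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 1) random non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    return "".join(codons) + stop


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[int(rng.integers(3))]
    return "".join(chars)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# parent genes


@dataclass
class _ParentGene:
    idx: int
    gene_id: str
    cds_codons: int
    exon_seqs: list[str]
    intron_seqs: list[str]
    mrna: str  # 5'UTR + CDS + stop + 3'UTR, spliced
    utr: int
    # intronic retro insertions: (intron_index, offset_within_intron, meta)
    insertions: list[tuple[int, int, "_Retro"]] = field(default_factory=list)

    def apply_insertions(self) -> None:
        # rebuild each intron once; earlier insertions shift later ones, so
        # final offsets are computed analytically, not by sequential editing
        by_intron: dict[int, list[tuple[int, _Retro]]] = {}
        for intron_idx, offset, retro in self.insertions:
            by_intron.setdefault(intron_idx, []).append((offset, retro))
        final_offsets: dict[int, int] = {}
        for idx, items in by_intron.items():
            items.sort(key=lambda x: x[0])
            intron = self.intron_seqs[idx]
            parts: list[str] = []
            prev = shift = 0
            for offset, retro in items:
                parts.append(intron[prev:offset])
                final_offsets[id(retro)] = offset + shift
                parts.append(retro.genomic_seq)
                shift += len(retro.genomic_seq)
                prev = offset
            parts.append(intron[prev:])
            self.intron_seqs[idx] = "".join(parts)
        for intron_idx, offset, retro in self.insertions:
            retro.local_gene_offset = (
                self._local_intron_start(intron_idx) + final_offsets[id(retro)]
            )

    def _local_intron_start(self, intron_idx: int) -> int:
        pos = 0
        for i in range(intron_idx + 1):
            pos += len(self.exon_seqs[i])
            if i < intron_idx:
                pos += len(self.intron_seqs[i])
        return pos

    @property
    def seq(self) -> str:
        parts = []
        for i, e in enumerate(self.exon_seqs):
            parts.append(e)
            if i < len(self.intron_seqs):
                parts.append(self.intron_seqs[i])
        return "".join(parts)

    def local_exons(self) -> list[tuple[int, int]]:
        out = []
        pos = 0
        for i, e in enumerate(self.exon_seqs):
            out.append((pos, pos + len(e)))
            pos += len(e)
            if i < len(self.intron_seqs):
                pos += len(self.intron_seqs[i])
        return out

    def mrna_to_local(self, m: int) -> int:
        """Map a spliced-mRNA coordinate to a local genomic coordinate."""
        for (ls, le), consumed in zip(self.local_exons(), self._cumlens()):
            if m < consumed + (le - ls):
                return ls + (m - consumed)
        raise ValueError("mRNA coordinate out of range")

    def _cumlens(self) -> list[int]:
        out, c = [], 0
        for e in self.exon_seqs:
            out.append(c)
            c += len(e)
        return out

    def cds_local_intervals(self) -> list[tuple[int, int]]:
        """Local genomic intervals of the CDS (incl. stop codon)."""
        cds_start = self.utr
        cds_end = len(self.mrna) - self.utr
        out = []
        consumed = 0
        for ls, le in self.local_exons():
            elen = le - ls
            s = max(cds_start, consumed)
            e = min(cds_end, consumed + elen)
            if s < e:
                out.append((ls + (s - consumed), ls + (e - consumed)))
            consumed += elen
        return out


def make_parent_gene(config: SimulationConfig, rng: np.random.Generator, idx: int = 0) -> _ParentGene:
    """Generate one multi-exon protein-coding gene on the '+' strand."""
    n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    n_codons = int(rng.integers(config.cds_length_codons[0], config.cds_length_codons[1] + 1))
    utr = config.utr_length
    cds = _random_cds(rng, n_codons)
    mrna = _random_seq(rng, utr) + cds + _random_seq(rng, utr)
    # split the mRNA into n_exons pieces, each at least 30 bp
    cuts: list[int] = []
    while len(cuts) < n_exons - 1:
        c = int(rng.integers(30, len(mrna) - 30))
        if all(abs(c - x) >= 30 for x in cuts):
            cuts.append(c)
    bounds = [0] + sorted(cuts) + [len(mrna)]
    exon_seqs = [mrna[a:b] for a, b in zip(bounds, bounds[1:])]
    intron_seqs = [
        "GT" + _random_seq(rng, int(rng.integers(*config.intron_length))) + "AG"
        for _ in range(n_exons - 1)
    ]
    return _ParentGene(
        idx=idx,
        gene_id=f"PG{idx:04d}",
        cds_codons=n_codons,
        exon_seqs=exon_seqs,
        intron_seqs=intron_seqs,
        mrna=mrna,
        utr=utr,
    )


# ---------------------------------------------------------------------------
# retrotransposition


@dataclass
class _Retro:
    pseudo_id: str
    parent: _ParentGene
    seq: str  # mRNA orientation, polyA tract appended, edits applied
    strand: str
    cds_start: int  # in `seq` coordinates (mRNA orientation)
    cds_end: int
    frameshift: bool
    frameshift_fraction: float | None
    placement: str  # intergenic | intronic
    ancestral_mrna: str
    is_fusion_source: bool = False
    # filled during assembly
    genomic_seq: str = ""
    local_gene_offset: int = -1  # for intronic insertions
    spacer_idx: int = -1
    abs_start: int = -1

    @property
    def abs_end(self) -> int:
        return self.abs_start + len(self.seq)


def retropose(
    parent: _ParentGene,
    config: SimulationConfig,
    rng: np.random.Generator,
    pseudo_id: str,
    placement: str,
    frameshift: bool,
    strand: str | None = None,
    allow_indels: bool = True,
) -> _Retro:
    """Copy a parent's spliced mRNA into a retrocopy sequence.

    Appends an 8-20 bp poly-A tract, optionally plants a single-base
    deletion at a recorded CDS fraction, then applies substitutions at
    the configured divergence and short indels at the indel rate.
    """
    mrna = parent.mrna
    tract = "A" * int(rng.integers(8, 21))
    seq = mrna + tract
    cds_start = parent.utr
    cds_end = len(mrna) - parent.utr
    fs_fraction: float | None = None
    if frameshift:
        # single-base deletion at a codon boundary; the shifted frame is
        # truncated immediately so the disrupted ORF length is exactly the
        # recorded fraction of the parent ORF (no re-initiation ambiguity
        # from wherever the shifted frame would happen to stop)
        codon = int(rng.uniform(0.2, 0.8) * parent.cds_codons)
        fs_fraction = codon / parent.cds_codons
        pos = cds_start + 3 * codon
        seq = seq[:pos] + "TAA" + seq[pos + 4 :]
        cds_end -= 1
    seq = _substitute(rng, seq, config.divergence)
    if allow_indels and config.indel_rate > 0:
        out = []
        new_cs = cds_start
        new_ce = cds_end
        for i, ch in enumerate(seq):
            if rng.random() < config.indel_rate:
                if rng.random() < 0.5:  # deletion of this base
                    if i < cds_start:
                        new_cs -= 1
                    if i < cds_end:
                        new_ce -= 1
                    continue
                ins = _random_seq(rng, int(rng.integers(1, 4)))
                out.append(ch + ins)
                if i < cds_start:
                    new_cs += len(ins)
                if i < cds_end:
                    new_ce += len(ins)
            else:
                out.append(ch)
        seq = "".join(out)
        cds_start, cds_end = new_cs, new_ce
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    r = _Retro(
        pseudo_id=pseudo_id,
        parent=parent,
        seq=seq,
        strand=strand,
        cds_start=cds_start,
        cds_end=cds_end,
        frameshift=frameshift,
        frameshift_fraction=fs_fraction,
        placement=placement,
        ancestral_mrna=mrna,
    )
    r.genomic_seq = seq if strand == "+" else _revcomp(seq)
    return r


# ---------------------------------------------------------------------------
# top-level simulation


def simulate(config: SimulationConfig) -> Simulation:
    config.validate()
    rng = np.random.default_rng(config.seed)

    parents = [make_parent_gene(config, rng, idx=i) for i in range(config.n_parent_genes)]

    # --- plan pseudogenes -------------------------------------------------
    retros: list[_Retro] = []
    n_total = config.n_pseudogenes + config.fusion_count
    parent_choices = rng.integers(0, len(parents), size=n_total)
    n_frameshift = int(round(config.frameshift_fraction * config.n_pseudogenes))
    fs_flags = np.zeros(config.n_pseudogenes, dtype=bool)
    fs_flags[:n_frameshift] = True
    rng.shuffle(fs_flags)
    free_spacers = list(range(config.n_parent_genes + 1))
    rng.shuffle(free_spacers)

    for k in range(config.n_pseudogenes):
        parent = parents[int(parent_choices[k])]
        intronic = rng.random() < config.intronic_insertion_fraction
        placement = "intronic" if intronic else "intergenic"
        r = retropose(
            parent, config, rng,
            pseudo_id=f"PSG{k:04d}",
            placement=placement,
            frameshift=bool(fs_flags[k]),
        )
        if intronic:
            hosts = [
                g for g in parents
                if g.idx != parent.idx and len(g.intron_seqs) > 0
            ]
            host = hosts[int(rng.integers(len(hosts)))]
            intron_idx = int(rng.integers(len(host.intron_seqs)))
            offset = int(rng.integers(20, len(host.intron_seqs[intron_idx]) - 20))
            host.insertions.append((intron_idx, offset, r))
            r.local_gene_offset = -1  # set by apply_insertions
            r.spacer_idx = -1
            r.host = host  # type: ignore[attr-defined]
        else:
            if not free_spacers:
                raise RuntimeError("no intergenic space left")
            r.spacer_idx = free_spacers.pop()
        retros.append(r)

    # --- fusion-source pseudogenes (intergenic, '+', no indels) -----------
    fusion_retros: list[_Retro] = []
    for k in range(config.fusion_count):
        # the retro must land downstream of its host gene so the fusion
        # splices 5'->3'; pick the spacer first, then a host upstream of it
        candidates = [s for s in free_spacers if s >= 1]
        if not candidates:
            raise RuntimeError("no intergenic space left for fusion retrocopies")
        spacer = candidates[int(rng.integers(len(candidates)))]
        free_spacers.remove(spacer)
        host = parents[int(rng.integers(0, spacer))]
        r = retropose(
            parents[int(parent_choices[config.n_pseudogenes + k])],
            config, rng,
            pseudo_id=f"PSGF{k:02d}",
            placement="intergenic",
            frameshift=False,
            strand="+",
            allow_indels=False,
        )
        r.is_fusion_source = True
        r.spacer_idx = spacer
        r.fusion_host = host  # type: ignore[attr-defined]
        retros.append(r)
        fusion_retros.append(r)

    for g in parents:
        g.apply_insertions()

    # --- assemble the chromosome -----------------------------------------
    by_spacer = {r.spacer_idx: r for r in retros if r.spacer_idx >= 0}
    parts: list[str] = []
    offset = 0
    gene_abs: dict[int, int] = {}

    def _emit_spacer(idx: int) -> None:
        nonlocal offset
        left = _random_seq(rng, int(rng.integers(800, 1500)))
        parts.append(left)
        offset += len(left)
        if idx in by_spacer:
            r = by_spacer[idx]
            r.abs_start = offset
            parts.append(r.genomic_seq)
            offset += len(r.genomic_seq)
        right = _random_seq(rng, int(rng.integers(800, 1500)))
        parts.append(right)
        offset += len(right)

    for g in parents:
        _emit_spacer(g.idx)
        gene_abs[g.idx] = offset
        gseq = g.seq
        parts.append(gseq)
        offset += len(gseq)
    _emit_spacer(config.n_parent_genes)

    chrom = list("".join(parts))

    for r in retros:
        if r.spacer_idx < 0:  # intronic
            host = r.host  # type: ignore[attr-defined]
            r.abs_start = gene_abs[host.idx] + r.local_gene_offset

    # --- reference annotation --------------------------------------------
    genes: list[GeneModel] = []
    pseudo_records: dict[str, PseudogeneRecord] = {}
    for g in parents:
        base = gene_abs[g.idx]
        exons = [
            GenomicInterval(CHROM, base + s, base + e, "+")
            for s, e in g.local_exons()
        ]
        cds = [
            GenomicInterval(CHROM, base + s, base + e, "+")
            for s, e in g.cds_local_intervals()
        ]
        tx = TranscriptModel(id=f"{g.gene_id}.t1", exons=exons)
        genes.append(
            GeneModel(
                id=g.gene_id, name=g.gene_id, biotype=Biotype.protein_coding,
                transcripts=[tx], cds=cds,
            )
        )
    for r in retros:
        iv = GenomicInterval(CHROM, r.abs_start, r.abs_end, r.strand)
        tx = TranscriptModel(id=f"{r.pseudo_id}.t1", exons=[iv])
        gm = GeneModel(
            id=r.pseudo_id, name=r.pseudo_id,
            biotype=Biotype.processed_pseudogene, transcripts=[tx],
        )
        genes.append(gm)
        pseudo_records[r.pseudo_id] = PseudogeneRecord(
            gene=gm, parent_gene_id=r.parent.gene_id, retro_interval=iv
        )

    truth = TruthManifest()
    for r in retros:
        truth.pseudogenes.append(
            PseudogeneTruth(
                pseudogene_id=r.pseudo_id,
                parent_id=r.parent.gene_id,
                locus=GenomicInterval(CHROM, r.abs_start, r.abs_end, r.strand),
                strand=r.strand,
                divergence=config.divergence,
                frameshift=r.frameshift,
                frameshift_cds_fraction=r.frameshift_fraction,
                placement=r.placement,
                host_gene_id=(r.host.gene_id if r.spacer_idx < 0 else None),  # type: ignore[attr-defined]
                parent_orf_aa=r.parent.cds_codons,
                is_fusion_source=r.is_fusion_source,
            )
        )

    # --- transcripts ------------------------------------------------------
    txs, abundance = plant_transcripts(
        parents, retros, gene_abs, chrom, truth, config, rng
    )

    genome = {CHROM: "".join(chrom)}

    # --- CAGE -------------------------------------------------------------
    peaks, signal = plant_cage(truth, genome, config, rng)

    # --- conservation inputs ---------------------------------------------
    cdnas: dict[str, str] = {}
    windows: dict[str, str] = {}
    for r in retros:
        if r.is_fusion_source:
            continue
        cdnas[r.pseudo_id] = r.seq[r.cds_start : r.cds_end]
        anc_cds = r.ancestral_mrna[r.parent.utr : len(r.ancestral_mrna) - r.parent.utr]
        body, stop = anc_cds[:-3], anc_cds[-3:]
        evolved = simulate_codon_divergence(
            body, config.ortholog_t, config.ortholog_omega, rng
        )
        utr5 = _substitute(rng, r.ancestral_mrna[: r.parent.utr], config.ortholog_t)
        utr3 = _substitute(rng, r.ancestral_mrna[len(r.ancestral_mrna) - r.parent.utr :], config.ortholog_t)
        windows[r.pseudo_id] = (
            _random_seq(rng, 1000) + utr5 + evolved + stop + utr3 + _random_seq(rng, 1000)
        )

    return Simulation(
        config=config,
        genome=genome,
        genes=genes,
        pseudogene_records=pseudo_records,
        transcripts=txs,
        abundance=abundance,
        cage_peaks=peaks,
        cage_signal=signal,
        cdnas=cdnas,
        ortholog_windows=windows,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# transcript planting


def _draw_fl(config: SimulationConfig, rng: np.random.Generator) -> int:
    p = config.fl_count_distribution.get("geometric_p", 0.45)
    lo = config.fl_count_distribution.get("min", 1)
    return int(lo + rng.geometric(p) - 1)


def _sanitise_and_plant(
    chrom: list[str],
    tx: TranscriptModel,
    window: int,
    motif: str,
    offset: int,
) -> None:
    """Clear the 3' window of incidental polyA motifs, then implant one.

    The window is genomic, ends at the transcript's terminal base, and is
    edited in transcript orientation; edits stay within the window, which
    the caller guarantees lies in UTR/poly-A/spacer sequence.
    """
    if tx.strand == "+":
        g_start, g_end = tx.end - window, tx.end
    else:
        g_start, g_end = tx.start, tx.start + window
    win = "".join(chrom[g_start:g_end])
    if tx.strand == "-":
        win = _revcomp(win)
    for _ in range(50):
        planted_span = range(window - offset - 6, window - offset)
        dirty = False
        for m in _MOTIFS:
            pos = win.find(m)
            while pos >= 0:
                if pos != planted_span.start or m != motif:
                    win = win[:pos] + _SAFE_HEXAMER + win[pos + 6 :]
                    dirty = True
                pos = win.find(m, pos + 1)
        win = win[: planted_span.start] + motif + win[planted_span.stop :]
        # verify: scanning must recover exactly the planted call
        found = None
        for m in _MOTIFS:
            p = win.rfind(m)
            if p >= 0:
                found = (m, window - (p + 6))
                break
        if found == (motif, offset) and not dirty:
            break
    back = win if tx.strand == "+" else _revcomp(win)
    chrom[g_start:g_end] = list(back)


def plant_transcripts(
    parents: list[_ParentGene],
    retros: list[_Retro],
    gene_abs: dict[int, int],
    chrom: list[str],
    truth: TruthManifest,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[TranscriptModel], dict[str, int]]:
    txs: list[TranscriptModel] = []
    abundance: dict[str, int] = {}

    def add(tx: TranscriptModel, t: TranscriptTruth) -> None:
        tx.fl_read_count = t.fl_read_count
        abundance[tx.id] = t.fl_read_count
        txs.append(tx)
        truth.transcripts.append(t)

    # parent mRNAs
    for g in parents:
        base = gene_abs[g.idx]
        exons = [GenomicInterval(CHROM, base + s, base + e, "+") for s, e in g.local_exons()]
        tx = TranscriptModel(id=f"tx_parent_{g.gene_id}", exons=exons)
        fl = _draw_fl(config, rng)
        add(tx, TranscriptTruth(
            tx_id=tx.id, label="parent_mRNA", tss=exons[0].start, strand="+",
            fl_read_count=fl, host_gene_id=g.gene_id,
        ))

    # pseudogene transcripts
    for r in retros:
        if r.is_fusion_source:
            continue
        iv = GenomicInterval(CHROM, r.abs_start, r.abs_end, r.strand)
        sense_tx = TranscriptModel(id=f"tx_sense_{r.pseudo_id}", exons=[iv])
        label = "dependent_intronic" if r.placement == "intronic" else "independent_sense"
        motif = _MOTIFS[int(rng.integers(2))]
        off = int(rng.integers(config.polya_motif_offset[0], config.polya_motif_offset[1] + 1))
        _sanitise_and_plant(chrom, sense_tx, 100, motif, off)
        tss = iv.start if r.strand == "+" else iv.end - 1
        add(sense_tx, TranscriptTruth(
            tx_id=sense_tx.id, label=label, tss=tss, strand=r.strand,
            fl_read_count=_draw_fl(config, rng), pseudogene_id=r.pseudo_id,
            polya_motif=motif, polya_offset=off,
            host_gene_id=(r.host.gene_id if r.spacer_idx < 0 else None),  # type: ignore[attr-defined]
        ))

        if r.placement == "intergenic":
            # novel 5' exon isoform from an upstream promoter
            if rng.random() < config.novel_five_prime_exon_fraction:
                gap = int(rng.integers(100, 300))
                if r.strand == "+":
                    ne = GenomicInterval(CHROM, iv.start - gap - 60, iv.start - gap, "+")
                    exons = [ne, iv]
                    n_tss = ne.start
                else:
                    ne = GenomicInterval(CHROM, iv.end + gap, iv.end + gap + 60, "-")
                    exons = [GenomicInterval(CHROM, iv.start, iv.end, "-"), ne]
                    n_tss = ne.end - 1
                ntx = TranscriptModel(id=f"tx_novel5_{r.pseudo_id}", exons=exons)
                add(ntx, TranscriptTruth(
                    tx_id=ntx.id, label="independent_sense", tss=n_tss, strand=r.strand,
                    fl_read_count=_draw_fl(config, rng), pseudogene_id=r.pseudo_id,
                    polya_motif=motif, polya_offset=off,
                ))
            # antisense transcript
            if rng.random() < config.antisense_fraction:
                a_strand = "-" if r.strand == "+" else "+"
                atx = TranscriptModel(
                    id=f"tx_anti_{r.pseudo_id}",
                    exons=[GenomicInterval(CHROM, iv.start, iv.end, a_strand)],
                )
                a_motif = _MOTIFS[int(rng.integers(2))]
                a_off = int(rng.integers(config.polya_motif_offset[0], config.polya_motif_offset[1] + 1))
                _sanitise_and_plant(chrom, atx, 100, a_motif, a_off)
                a_tss = iv.end - 1 if a_strand == "-" else iv.start
                add(atx, TranscriptTruth(
                    tx_id=atx.id, label="independent_antisense", tss=a_tss,
                    strand=a_strand, fl_read_count=_draw_fl(config, rng),
                    pseudogene_id=r.pseudo_id, polya_motif=a_motif, polya_offset=a_off,
                ))

    # fusion transcripts
    for r in retros:
        if not r.is_fusion_source:
            continue
        host = r.fusion_host  # type: ignore[attr-defined]
        base = gene_abs[host.idx]
        # keep ~60% of the host CDS, cut at a codon boundary
        keep = 3 * max(1, int(0.6 * host.cds_codons))
        cut_local = host.mrna_to_local(host.utr + keep)
        exons: list[GenomicInterval] = []
        for s, e in host.local_exons():
            if e <= cut_local:
                exons.append(GenomicInterval(CHROM, base + s, base + e, "+"))
            elif s < cut_local:
                exons.append(GenomicInterval(CHROM, base + s, base + cut_local, "+"))
        # retro exon: tail of the retro CDS (incl. stop) + 30 bp of 3'UTR,
        # capped so the host exons keep the greater overlap and the
        # transcript is assigned to the host gene, not the pseudogene
        host_overlap = config.utr_length + keep
        retro_codons = r.parent.cds_codons
        tail_codons = max(10, min((host_overlap - 83) // 3, retro_codons - 1))
        jc = 3 * (retro_codons - tail_codons)  # nt offset into CDS, codon-aligned
        b_start = r.abs_start + r.cds_start + jc
        b_end = r.abs_start + r.cds_end + 30
        exons.append(GenomicInterval(CHROM, b_start, b_end, "+"))
        ftx = TranscriptModel(id=f"tx_fusion_{r.pseudo_id}", exons=exons)
        genome_view = {CHROM: "".join(chrom)}
        orf = find_longest_orf(ftx.spliced_sequence(genome_view))
        n_codons = 0
        if orf is not None:
            ri = GenomicInterval(CHROM, r.abs_start, r.abs_end, r.strand)
            for bases in codon_genomic_positions(ftx, orf):
                if sum(1 for p in bases if ri.start <= p < ri.end) >= 2:
                    n_codons += 1
        fl = max(2, _draw_fl(config, rng))
        add(ftx, TranscriptTruth(
            tx_id=ftx.id, label="fusion", tss=exons[0].start, strand="+",
            fl_read_count=fl, pseudogene_id=r.pseudo_id,
            host_gene_id=host.gene_id, fusion_codons=n_codons,
        ))

    return txs, abundance


def plant_cage(
    truth: TruthManifest,
    genome: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[GenomicInterval], dict[str, dict[int, float]]]:
    """Peaks of configured width centred at each planted TSS plus jitter,
    background peaks at random loci, and per-base signal over every peak."""
    half = config.cage_peak_width // 2
    chrom_len = len(genome[CHROM])
    peaks: list[GenomicInterval] = []
    signal: dict[int, float] = {}
    for t in truth.transcripts:
        j = int(round(rng.normal(0.0, config.cage_jitter_sd))) if config.cage_jitter_sd > 0 else 0
        s = max(0, t.tss - half + j)
        e = min(chrom_len, t.tss + half + j)
        if s >= e:
            continue
        peaks.append(GenomicInterval(CHROM, s, e, "."))
        for p in range(s, e):
            signal[p] = signal.get(p, 0.0) + config.cage_depth
    for _ in range(config.cage_background_peaks):
        s = int(rng.integers(0, chrom_len - config.cage_peak_width))
        peaks.append(GenomicInterval(CHROM, s, s + config.cage_peak_width, "."))
        for p in range(s, s + config.cage_peak_width):
            signal[p] = signal.get(p, 0.0) + config.cage_depth
    return peaks, {CHROM: signal}


# ---------------------------------------------------------------------------
# emission


def emit(sim: Simulation, outdir: str | Path) -> dict[str, Path]:
    """Write every simulation product as plain-text files; byte-identical
    for identical (config, seed)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "annotation.gtf",
        "retro": out / "retrocopies.bed",
        "transcripts": out / "transcripts.bed12",
        "abundance": out / "abundance.tsv",
        "cage_peaks": out / "cage_peaks.bed",
        "cage_signal": out / "cage_signal.bedgraph",
        "cdna": out / "pseudogene_cdna.fa",
        "windows": out / "ortholog_windows.fa",
        "truth_json": out / "truth.json",
        "truth_transcripts": out / "truth_transcripts.tsv",
        "truth_pseudogenes": out / "truth_pseudogenes.tsv",
    }
    write_fasta(sim.genome, paths["genome"])
    write_gtf(sim.genes, paths["annotation"])
    write_bed6(
        [
            (rec.gene.id, rec.retro_interval, 0)
            for rec in sim.pseudogene_records.values()
        ],
        paths["retro"],
    )
    write_bed12(sim.transcripts, paths["transcripts"])
    with open(paths["abundance"], "w") as fh:
        fh.write("transcript_id\tfl_count\n")
        for k in sorted(sim.abundance):
            fh.write(f"{k}\t{sim.abundance[k]}\n")
    write_bed6(
        [(f"peak{i}", iv, 1) for i, iv in enumerate(sim.cage_peaks)],
        paths["cage_peaks"],
    )
    write_bedgraph(sim.cage_signal, paths["cage_signal"])
    write_fasta(sim.cdnas, paths["cdna"])
    write_fasta(sim.ortholog_windows, paths["windows"])

    def _clean(d: dict) -> dict:
        return {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in d.items()
        }

    with open(paths["truth_json"], "w") as fh:
        json.dump(
            {
                "pseudogenes": [_clean(dataclasses.asdict(p)) for p in sim.truth.pseudogenes],
                "transcripts": [dataclasses.asdict(t) for t in sim.truth.transcripts],
            },
            fh,
            indent=1,
        )
    write_tsv_report(
        [dataclasses.asdict(t) for t in sim.truth.transcripts],
        paths["truth_transcripts"],
    )
    write_tsv_report(
        [
            {**dataclasses.asdict(p), "locus": f"{p.locus.chrom}:{p.locus.start}-{p.locus.end}"}
            for p in sim.truth.pseudogenes
        ],
        paths["truth_pseudogenes"],
    )
    return paths
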