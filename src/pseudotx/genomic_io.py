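"""Readers/writers for the genomic file formats the pipeline touches.

All coordinates are normalised to a single internal convention: 0-based,
half-open ``[start, end)``. GTF (1-based, closed) is converted on read and
write; BED and bedGraph already use the internal convention and pass
through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_IUPAC = set("ACGTRYSWKMBDHVN")


class Biotype(str, Enum):
    protein_coding = "protein_coding"
    processed_pseudogene = "processed_pseudogene"
    unprocessed_pseudogene = "unprocessed_pseudogene"
    lncRNA = "lncRNA"
    other = "other"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with a strand ('+', '-' or '.')."""

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

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """An exon chain on one chromosome strand with full-length read support.

    Exons are sorted by start and non-overlapping; ``sequence``, when set,
    is the spliced sequence in transcript (5'->3') orientation.
    """

    id: str
    exons: list[GenomicInterval]
    fl_read_count: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"transcript {self.id}: exons on multiple chroms")
        if len(strands) != 1 or strands <= {"."}:
            raise ValueError(f"transcript {self.id}: exons need one strand in {{+,-}}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        if self.fl_read_count < 0:
            raise ValueError("fl_read_count must be non-negative")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Extract the spliced transcript sequence, reverse-complemented for '-'."""
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[e.start : e.end] for e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class GeneModel:
    id: str
    name: str
    biotype: Biotype
    transcripts: list[TranscriptModel] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.start for t in self.transcripts)
        end = max(t.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def exon_intervals(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]


@dataclass
class PseudogeneRecord:
    """A pseudogene gene model with parent linkage and its retrocopy interval.

    The record's strand is the retrocopy's annotated orientation, which
    equals the orientation of the parent mRNA at the insertion site.
    """

    gene: GeneModel
    parent_gene_id: str
    retro_interval: GenomicInterval

    @property
    def strand(self) -> str:
        return self.gene.strand


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an id -> sequence mapping.

    Sequences are uppercased and U is converted to T. Duplicate ids, empty
    records and non-IUPAC characters are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        s = str(rec.seq).upper().replace("U", "T")
        if not s:
            raise ValueError(f"empty record {rec.id!r}")
        for i, c in enumerate(s):
            if c not in _IUPAC:
                raise ValueError(f"non-IUPAC character {c!r} at {rec.id}:{i}")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF (Gencode attribute dialect)

_KNOWN_BIOTYPES = {b.value for b in Biotype} - {"other"}


def _coerce_biotype(raw: str | None) -> Biotype:
    if raw in _KNOWN_BIOTYPES:
        return Biotype(raw)
    log.warning("unknown biotype %r mapped to 'other'", raw)
    return Biotype.other


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a Gencode-dialect GTF into gene models.

    1-based closed GTF coordinates become 0-based half-open. Both
    ``gene_type`` and ``gene_biotype`` attribute keys are accepted;
    unknown biotypes map to :attr:`Biotype.other` with a warning.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        raw_bt = (g.attributes.get("gene_type") or g.attributes.get("gene_biotype") or [None])[0]
        name = (g.attributes.get("gene_name") or [g.id])[0]
        transcripts: list[TranscriptModel] = []
        cds: list[GenomicInterval] = []
        for t in db.children(g, featuretype="transcript"):
            exons = []
            for e in db.children(t, featuretype="exon"):
                if "transcript_id" not in e.attributes:
                    raise ValueError(f"exon without transcript_id near {e.seqid}:{e.start}")
                if e.seqid != t.seqid:
                    raise ValueError(f"transcript {t.id} spans multiple chroms")
                exons.append(GenomicInterval(e.seqid, e.start - 1, e.end, e.strand))
            if exons:
                transcripts.append(TranscriptModel(id=t.id, exons=exons))
            for c in db.children(t, featuretype="CDS"):
                cds.append(GenomicInterval(c.seqid, c.start - 1, c.end, c.strand))
        genes.append(
            GeneModel(
                id=g.id,
                name=name,
                biotype=_coerce_biotype(raw_bt),
                transcripts=transcripts,
                cds=sorted(cds, key=lambda i: i.start),
            )
        )
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "pseudotx") -> None:
    """Write gene models as Gencode-dialect GTF (internal 0-based -> 1-based closed)."""

    def attrs(**kv: str) -> str:
        return " ".join(f'{k} "{v}";' for k, v in kv.items())

    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            fh.write(
                "\t".join(
                    [
                        span.chrom,
                        source,
                        "gene",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        span.strand,
                        ".",
                        attrs(gene_id=g.id, gene_name=g.name, gene_type=g.biotype.value),
                    ]
                )
                + "\n"
            )
            for t in g.transcripts:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "transcript",
                            str(t.start + 1),
                            str(t.end),
                            ".",
                            t.strand,
                            ".",
                            attrs(
                                gene_id=g.id,
                                transcript_id=t.id,
                                gene_name=g.name,
                                gene_type=g.biotype.value,
                            ),
                        ]
                    )
                    + "\n"
                )
                for e in t.exons:
                    fh.write(
                        "\t".join(
                            [
                                e.chrom,
                                source,
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                e.strand,
                                ".",
                                attrs(gene_id=g.id, transcript_id=t.id, gene_type=g.biotype.value),
                            ]
                        )
                        + "\n"
                    )
                for c in g.cds:
                    fh.write(
                        "\t".join(
                            [
                                c.chrom,
                                source,
                                "CDS",
                                str(c.start + 1),
                                str(c.end),
                                ".",
                                c.strand,
                                "0",
                                attrs(gene_id=g.id, transcript_id=t.id, gene_type=g.biotype.value),
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# BED

_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def read_bed(path: str | Path, blocked: bool = False) -> list:
    """Read BED6 (peaks/retrocopies) or, with ``blocked=True``, BED12 transcripts.

    BED is 0-based half-open already; BED12 blocks are expanded to exon
    chains (blockStarts relative to chromStart).
    """
    ncols = 12 if blocked else 6
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=_BED12_COLS[:ncols], dtype={"chrom": str, "name": str},
    )
    out = []
    for row in df.itertuples(index=False):
        if row.start < 0:
            raise ValueError(f"negative chromStart for {row.name}")
        if not blocked:
            out.append(GenomicInterval(row.chrom, int(row.start), int(row.end), str(row.strand)))
            continue
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != int(row.blockCount) or len(starts) != int(row.blockCount):
            raise ValueError(f"blockCount mismatch for {row.name}")
        exons = [
            GenomicInterval(row.chrom, int(row.start) + s, int(row.start) + s + sz, str(row.strand))
            for s, sz in zip(starts, sizes)
        ]
        out.append(TranscriptModel(id=str(row.name), exons=exons))
    return out


def write_bed12(txs: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in txs:
            sizes = ",".join(str(len(e)) for e in t.exons)
            starts = ",".join(str(e.start - t.start) for e in t.exons)
            fh.write(
                "\t".join(
                    [
                        t.chrom, str(t.start), str(t.end), t.id, str(t.fl_read_count),
                        t.strand, str(t.start), str(t.start), "0",
                        str(len(t.exons)), sizes, starts,
                    ]
                )
                + "\n"
            )


def write_bed6(intervals: Iterable[tuple[str, GenomicInterval, float]], path: str | Path) -> None:
    """Write (name, interval, score) triples as BED6."""
    with open(path, "w") as fh:
        for name, iv, score in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph (4-column per-base CAGE signal)


def read_bedgraph(path: str | Path) -> dict[str, dict[int, float]]:
    """Read a bedGraph into per-chrom sparse position -> value maps."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"], dtype={"chrom": str})
    signal: dict[str, dict[int, float]] = {}
    for row in df.itertuples(index=False):
        d = signal.setdefault(row.chrom, {})
        for pos in range(int(row.start), int(row.end)):
            d[pos] = float(row.value)
    return signal


def write_bedgraph(signal: Mapping[str, Mapping[int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(signal):
            d = signal[chrom]
            run_start = run_val = None
            prev = None
            for pos in sorted(d):
                v = d[pos]
                if run_start is not None and (pos != prev + 1 or v != run_val):
                    fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val:g}\n")
                    run_start = None
                if run_start is None:
                    run_start, run_val = pos, v
                prev = pos
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val:g}\n")


# ---------------------------------------------------------------------------
# TSV reports and abundance tables


def write_tsv_report(records: Sequence[Mapping], path: str | Path) -> None:
    """Write records sharing a schema as a TSV with a deterministic header."""
    if records:
        cols = list(records[0].keys())
        for r in records:
            if list(r.keys()) != cols:
                raise ValueError("records do not share a schema")
        df = pd.DataFrame(list(records), columns=cols)
    else:
        df = pd.DataFrame()
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_abundance(path: str | Path) -> dict[str, int]:
    """Read a two-column transcript-id / full-length-count TSV."""
    df = pd.read_csv(path, sep="\t")
    id_col, count_col = df.columns[0], df.columns[1]
    return {str(r[id_col]): int(r[count_col]) for _, r in df.iterrows()}
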