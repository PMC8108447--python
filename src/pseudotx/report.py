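"""Cohort-level summaries, percentage formatting and small expression utilities.

Percentages follow the convention of the source literature for fractions
of this kind: values below 10% print one decimal place, larger values
print to the nearest integer, both rounding half up. Stored counts stay
exact; the rule is presentation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .conservation import DnDsEstimate, dnds_summary
from .classifier import ClassifiedTranscript, Independence, Orientation
from .features import PolyACall, PolyAMotif, TssSupport
from .orfs import OrfRecord


def format_percent(numerator: int, denominator: int) -> tuple[str, str]:
    """Render a count fraction as ('n/d', '(X%)') in the house style."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    if value < 10:
        rendered = str(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    else:
        rendered = str(value.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return f"{numerator}/{denominator}", f"({rendered}%)"


def percent_str(numerator: int, denominator: int) -> str:
    frac, pct = format_percent(numerator, denominator)
    return f"{frac} {pct}"


@dataclass
class SummaryReport:
    n_transcripts: int = 0
    n_pseudogenes_overlapped: int = 0
    n_independent_sense: int = 0
    n_independent_antisense: int = 0
    n_multi_exonic: int = 0
    n_sharing_junctions: int = 0
    n_polya_positive: int = 0
    n_cage_supported: int = 0
    n_orf_gt100: int = 0
    n_orf_ge90pct_parent: int = 0
    dnds: tuple[int, int, float | None, float | None] = (0, 0, None, None)
    formatted: dict[str, str] = field(default_factory=dict)


def summarize(
    classified: Sequence[ClassifiedTranscript],
    features: Mapping[str, tuple[TssSupport, PolyACall]] | None = None,
    orfs: Mapping[str, tuple[OrfRecord | None, float]] | None = None,
    dnds: Sequence[DnDsEstimate] = (),
) -> SummaryReport:
    """Aggregate per-transcript calls into the cohort-level report.

    ``features`` maps transcript id -> (TssSupport, PolyACall); ``orfs``
    maps transcript id -> (OrfRecord or None, parent ORF fraction). Ids
    in those mappings must exist in ``classified``.
    """
    rep = SummaryReport()
    pseudo_txs = [c for c in classified if c.is_pseudogene_transcript]
    known = {c.tx.id for c in classified}
    for mapping in (features, orfs):
        if mapping:
            missing = set(mapping) - known
            if missing:
                raise ValueError(f"feature ids not in classified cohort: {sorted(missing)[:3]}")
    rep.n_transcripts = len(pseudo_txs)
    rep.n_pseudogenes_overlapped = len({c.assigned_gene_id for c in pseudo_txs})
    rep.n_independent_sense = sum(
        1 for c in pseudo_txs
        if c.independence is Independence.independent and c.orientation is Orientation.sense
    )
    rep.n_independent_antisense = sum(
        1 for c in pseudo_txs
        if c.independence is Independence.independent and c.orientation is Orientation.antisense
    )
    rep.n_multi_exonic = sum(1 for c in pseudo_txs if c.multi_exonic)
    rep.n_sharing_junctions = sum(
        1 for c in pseudo_txs if c.multi_exonic and c.shares_reference_junction
    )
    if features:
        for c in pseudo_txs:
            if c.tx.id not in features:
                continue
            tss_sup, polya = features[c.tx.id]
            if tss_sup.supported:
                rep.n_cage_supported += 1
            if polya.motif is not PolyAMotif.none:
                rep.n_polya_positive += 1
    if orfs:
        for c in pseudo_txs:
            if c.tx.id not in orfs:
                continue
            orf, frac = orfs[c.tx.id]
            if orf is not None and orf.aa_length > 100:
                rep.n_orf_gt100 += 1
            if frac >= 0.9:
                rep.n_orf_ge90pct_parent += 1
    rep.dnds = dnds_summary(dnds)
    n = rep.n_transcripts
    if n:
        rep.formatted = {
            "independent_sense": percent_str(rep.n_independent_sense, n),
            "independent_antisense": percent_str(rep.n_independent_antisense, n),
            "polya_positive": percent_str(rep.n_polya_positive, n),
            "cage_supported": percent_str(rep.n_cage_supported, n),
            "orf_gt100": percent_str(rep.n_orf_gt100, n),
        }
        rep.formatted["sharing_junctions"] = (
            percent_str(rep.n_sharing_junctions, rep.n_multi_exonic)
            if rep.n_multi_exonic
            else "n/a"
        )
        n_def, n_pur, _, med = rep.dnds
        rep.formatted["dnds_purifying"] = (
            f"{percent_str(n_pur, n_def)}, median {med:.4f}" if n_def else "n/a"
        )
    return rep


def ct_enrichment(ct_nuclear: float, ct_cytoplasmic: float, direction: str) -> float:
    """qPCR compartment enrichment from raw Ct values.

    nuclear enrichment = 2^(Ct_cyt - Ct_nuc); cytoplasmic is the inverse.
    """
    if not (math.isfinite(ct_nuclear) and math.isfinite(ct_cytoplasmic)):
        raise ValueError("Ct values must be finite")
    if direction == "nuclear":
        return 2.0 ** (ct_cytoplasmic - ct_nuclear)
    if direction == "cytoplasmic":
        return 2.0 ** (ct_nuclear - ct_cytoplasmic)
    raise ValueError(f"unknown direction {direction!r}")


def counts_to_logcpm(counts) -> np.ndarray:
    """log2(cpm + 1) per column (sample); no between-sample normalisation."""
    m = np.asarray(counts, dtype=float)
    if (m < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = m.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("zero library size column")
    cpm = m / libsize * 1e6
    return np.log2(cpm + 1.0)
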