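"""Selection analysis on pseudogene ORFs.

The pipeline locates the orthologous cDNA of a pseudogene ORF inside a
flanked genomic window from a second species, translates both copies,
aligns the proteins globally, threads the cDNAs through the protein
alignment, and estimates pairwise dN/dS by Nei-Gojobori (1986) counting
with Jukes-Cantor correction:

    pS = Sd / S,  pN = Nd / N,
    d  = -(3/4) * ln(1 - (4/3) * p),   omega = dN / dS.

Synonymous-site fractions come from the standard genetic code; mutations
to stop codons count as nonsynonymous, and multi-hit codon differences
are averaged over all mutational pathways that avoid stop codons (over
all pathways if none avoids them). omega < 1 indicates purifying
selection, omega > 1 diversifying selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .alignment import (
    CodonAlignment,
    LocalAlignmentResult,
    ProteinAlignment,
    global_protein_align,
    smith_waterman,
    thread_codons,
)
from .genomic_io import TranscriptModel
from .orfs import STOP_CODONS, translate

_BASES = "ACGT"

# codon -> amino acid ('*' for stops), precomputed for the hot NG86 loops
_CODON_AA: dict[str, str] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _c = _b1 + _b2 + _b3
            _CODON_AA[_c] = "*" if _c in STOP_CODONS else translate(_c)


@dataclass
class DnDsEstimate:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    n_codons: int = 0
    n_diffs: int = 0

    @property
    def status(self) -> str:
        # sufficient nucleotide diversity: >= 1 observed difference with a
        # defined, nonzero synonymous distance
        if self.n_diffs < 1 or self.dS is None or self.dS == 0:
            return "insufficient_diversity"
        return "defined" if self.omega is not None else "undefined"


def extract_flanked_window(
    tx: TranscriptModel, genome: Mapping[str, str], flank: int = 1000
) -> str:
    """Genomic span of the transcript plus ``flank`` on both ends, clipped
    to the chromosome and oriented to the transcript strand."""
    chrom_seq = genome[tx.chrom]
    start = max(0, tx.start - flank)
    end = min(len(chrom_seq), tx.end + flank)
    seq = chrom_seq[start:end]
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def locate_ortholog_cdna(
    cdna: str, window: str, min_score_fraction: float = 0.25
) -> LocalAlignmentResult:
    """Best local (splice-naive) placement of a cDNA inside a genomic window.

    Smith-Waterman with match +2, mismatch -3, gap open -5, extend -2.
    Short spurious matches are inevitable with a positive match score, so
    a hit must reach ``min_score_fraction`` of the perfect-match score
    (2 x cDNA length) to count; anything below — e.g. a window in the
    wrong orientation — raises "no ortholog found".
    """
    try:
        hit = smith_waterman(cdna, window)
    except ValueError:
        raise ValueError("no ortholog found")
    if hit.score < min_score_fraction * 2.0 * len(cdna):
        raise ValueError(
            f"no ortholog found (best score {hit.score:g} below threshold)"
        )
    return hit


def check_divisible_by_three(seq: str) -> bool:
    return len(seq) % 3 == 0


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three single-base changes at ``pos`` that are synonymous."""
    aa = _CODON_AA[codon]
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt in STOP_CODONS:
            continue  # change to stop: nonsynonymous
        if _CODON_AA[alt] == aa:
            syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(S, N) expected synonymous/nonsynonymous sites of one sense codon; S+N=3."""
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over mutational pathways.

    Pathways passing through stop codons are excluded unless all do.
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    through_stop: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        hits_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                hits_stop = True
                nd += 1  # to-stop steps are nonsynonymous
            elif cur in STOP_CODONS:
                hits_stop = True
                nd += 1
            elif _CODON_AA[nxt] == _CODON_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (through_stop if hits_stop else valid).append((sd, nd))
    pool = valid if valid else through_stop
    sd = sum(x for x, _ in pool) / len(pool)
    nd = sum(y for _, y in pool) / len(pool)
    return sd, nd


def ng86_dnds(codon_aln: CodonAlignment) -> DnDsEstimate:
    """Nei-Gojobori (1986) pairwise dN/dS from a codon alignment.

    Columns with gaps, ambiguous bases or stop codons are excluded.
    Sites are averaged over the two sequences; the Jukes-Cantor distance
    is undefined when p >= 3/4, and omega is undefined when dS is 0 or
    either distance is undefined.
    """
    s1 = s2 = 0.0
    sd = nd = 0.0
    n_codons = 0
    for c1, c2 in codon_aln.columns():
        if "-" in c1 or "-" in c2:
            continue
        if any(b not in _BASES for b in c1 + c2):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        n_codons += 1
        a, _ = codon_sites(c1)
        b, _ = codon_sites(c2)
        s1 += a
        s2 += b
        d_s, d_n = _pathway_counts(c1, c2)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise ValueError("no usable (ungapped, unambiguous) codon columns")
    S = (s1 + s2) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return DnDsEstimate(
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, dS=dS, dN=dN, omega=omega,
        n_codons=n_codons, n_diffs=int(round(sd + nd)),
    )


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def dnds_summary(
    estimates: Sequence[DnDsEstimate],
) -> tuple[int, int, float | None, float | None]:
    """(n_defined, n_purifying, fraction_purifying, median_omega).

    Purifying means omega strictly below 1; the median is the midpoint of
    the central pair for even counts. Estimates without a finite omega
    (insufficient diversity or undefined distances) are excluded.
    """
    omegas = sorted(e.omega for e in estimates if e.omega is not None)
    n = len(omegas)
    if n == 0:
        return 0, 0, None, None
    purifying = sum(1 for w in omegas if w < 1.0)
    mid = n // 2
    median = omegas[mid] if n % 2 else (omegas[mid - 1] + omegas[mid]) / 2.0
    return n, purifying, purifying / n, median


def pairwise_dnds(cdna: str, window: str) -> tuple[DnDsEstimate | None, str]:
    """Full per-transcript conservation pipeline against one ortholog window.

    Returns (estimate-or-None, status); statuses: ``defined``,
    ``undefined``, ``insufficient_diversity``, ``no_ortholog``,
    ``not_divisible_by_3``, ``no_orf``.
    """
    try:
        hit = locate_ortholog_cdna(cdna, window)
    except ValueError:
        return None, "no_ortholog"
    ortho = hit.aligned_target_subseq
    if not check_divisible_by_three(ortho) or not check_divisible_by_three(cdna):
        return None, "not_divisible_by_3"
    cd1, cd2 = _strip_terminal_stop(cdna), _strip_terminal_stop(ortho)
    p1, p2 = translate(cd1), translate(cd2)
    if "*" in p1 or "*" in p2:
        # internal stops break protein alignment; mask is out of scope here
        return None, "no_orf"
    if not p1 or not p2:
        return None, "no_orf"
    aln = global_protein_align(p1, p2)
    codon_aln = thread_codons(aln, cd1, cd2)
    est = ng86_dnds(codon_aln)
    return est, est.status


def _strip_terminal_stop(cdna: str) -> str:
    if len(cdna) >= 3 and cdna[-3:] in STOP_CODONS:
        return cdna[:-3]
    return cdna


def simulate_codon_divergence(
    cds: str,
    t: float,
    omega_true: float,
    seed: int | np.random.Generator,
) -> str:
    """Evolve a CDS under a simple codon model with selection strength omega.

    Substitutions are proposed uniformly over sites at expected rate ``t``
    per site (Poisson number of proposals); synonymous proposals are
    always accepted, nonsynonymous ones with probability ``omega_true``,
    and proposals creating stop codons are rejected. Deterministic under
    a fixed seed.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    prot = translate(cds)
    if "*" in prot:
        raise ValueError("CDS contains internal stop codons")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = list(cds.upper())
    n = len(seq)
    n_prop = rng.poisson(t * n)
    for _ in range(n_prop):
        pos = int(rng.integers(n))
        old = seq[pos]
        new = _BASES[int(rng.integers(4))]
        if new == old:
            continue
        ci = pos // 3
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        alt = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
        if alt in STOP_CODONS:
            continue
        accept = translate(alt) == translate(codon) or rng.random() < omega_true
        if accept:
            seq[pos] = new
    return "".join(seq)
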