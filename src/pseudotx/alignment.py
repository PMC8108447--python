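"""Pairwise sequence alignment primitives and codon threading.

Global protein alignment is Needleman-Wunsch with BLOSUM62 and affine
gaps; local nucleotide alignment is Smith-Waterman (Gotoh) with simple
match/mismatch scores. A gap of length k costs ``open + extend * k``
(the opening penalty is charged once, extension per base). Tracebacks
are deterministic: ties prefer diagonal, then up (gap in the second
sequence), then left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

NEG = -1e9

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class LocalAlignmentResult:
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    score: float
    aligned_target_subseq: str


@dataclass
class ProteinAlignment:
    rows: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.rows
        if len(a) != len(b):
            raise ValueError("alignment rows differ in length")
        if any(x == "-" and y == "-" for x, y in zip(a, b)):
            raise ValueError("all-gap column")


@dataclass
class CodonAlignment:
    rows: tuple[str, str]  # gapped codon strings; gap token '---'

    def __post_init__(self) -> None:
        a, b = self.rows
        if len(a) != len(b) or len(a) % 3 != 0:
            raise ValueError("codon rows must be equal length, divisible by 3")

    def columns(self) -> list[tuple[str, str]]:
        a, b = self.rows
        return [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]


def blosum62(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def global_protein_align(
    p1: str,
    p2: str,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> ProteinAlignment:
    """Needleman-Wunsch global alignment of two proteins, end gaps penalised.

    Affine gap of length k costs ``gap_open + gap_extend * k``. Traceback
    is deterministic (diagonal > up > left on ties).
    """
    if not p1 or not p2:
        raise ValueError("empty protein sequence")
    if "-" in p1 or "-" in p2:
        raise ValueError("input proteins must be ungapped")
    n, m = len(p1), len(p2)
    first = gap_open + gap_extend  # cost of a gap's first base
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in p2 (consumes p1; 'up')
    Y = np.full((n + 1, m + 1), NEG)  # gap in p1 (consumes p2; 'left')
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum62(p1[i - 1], p2[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + first, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + first, Y[i, j - 1] + gap_extend)
    # traceback from the best final state; diagonal > up > left on ties
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][n, m])
    # stable preference when scores tie:
    for cand in ("M", "X", "Y"):
        if {"M": M, "X": X, "Y": Y}[cand][n, m] == {"M": M, "X": X, "Y": Y}[state][n, m]:
            state = cand
            break
    r1: list[str] = []
    r2: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = blosum62(p1[i - 1], p2[j - 1])
            prev = M[i, j] - s
            r1.append(p1[i - 1])
            r2.append(p2[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for cand, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i, j] == prev:
                    state = cand
                    break
        elif state == "X":
            r1.append(p1[i - 1])
            r2.append("-")
            opened = X[i, j] == M[i - 1, j] + first
            i -= 1
            state = "M" if opened else "X"
            if i == 0 and j == 0:
                break
            if state == "X" and X[i, j] <= NEG / 2:
                state = "M"
        else:
            r1.append("-")
            r2.append(p2[j - 1])
            opened = Y[i, j] == M[i, j - 1] + first
            j -= 1
            state = "M" if opened else "Y"
            if j == 0 and i == 0:
                break
            if state == "Y" and Y[i, j] <= NEG / 2:
                state = "M"
    return ProteinAlignment(rows=("".join(reversed(r1)), "".join(reversed(r2))))


def global_alignment_score(
    p1: str, p2: str, gap_open: float = -11.0, gap_extend: float = -1.0
) -> float:
    """Optimal global alignment score (same model as global_protein_align)."""
    if not p1 or not p2:
        raise ValueError("empty protein sequence")
    n, m = len(p1), len(p2)
    first = gap_open + gap_extend
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum62(p1[i - 1], p2[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + first, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + first, Y[i, j - 1] + gap_extend)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def score_alignment(
    rows: tuple[str, str], gap_open: float = -11.0, gap_extend: float = -1.0
) -> float:
    """Score an explicit gapped protein alignment under the affine model."""
    a, b = rows
    score = 0.0
    in_gap: str | None = None
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            which = "a" if x == "-" else "b"
            score += gap_extend
            if in_gap != which:
                score += gap_open
            in_gap = which
        else:
            score += blosum62(x, y)
            in_gap = None
    return score


def smith_waterman(
    query: str,
    target: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> LocalAlignmentResult:
    """Smith-Waterman local alignment of a cDNA against a genomic window.

    Splice-naive; a gap of length k costs ``gap_open + gap_extend * k``.
    Runs on Biopython's C aligner; the highest-scoring region is returned
    (the aligner's first optimal alignment, which starts at the smallest
    target offset for exact hits). Raises if the best score is 0.
    """
    from Bio import Align

    q, t = query.upper(), target.upper()
    if not q or not t:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend  # first gap base
    aligner.extend_gap_score = gap_extend
    alns = aligner.align(q, t)
    if alns.score <= 0:
        raise ValueError("no ortholog found (best local score 0)")
    a = alns[0]
    q_blocks, t_blocks = a.aligned
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    t_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    return LocalAlignmentResult(
        query_span=q_span,
        target_span=t_span,
        score=float(alns.score),
        aligned_target_subseq=t[t_span[0] : t_span[1]],
    )


def thread_codons(aln: ProteinAlignment, cdna1: str, cdna2: str) -> CodonAlignment:
    """Expand a pairwise protein alignment to a codon alignment.

    Terminal stop codons must already be stripped; each cDNA must
    translate to its degapped protein row. Gap columns become '---'.
    """
    from .orfs import translate

    rows_out = []
    for row, cdna in ((aln.rows[0], cdna1), (aln.rows[1], cdna2)):
        degapped = row.replace("-", "")
        if len(cdna) != 3 * len(degapped):
            raise ValueError(
                f"cDNA length {len(cdna)} != 3 x protein length {len(degapped)}"
            )
        prot = translate(cdna)
        out = []
        k = 0
        for col, aa in enumerate(row):
            if aa == "-":
                out.append("---")
                continue
            if prot[k] != aa:
                raise ValueError(
                    f"translation mismatch at alignment column {col}: "
                    f"codon gives {prot[k]!r}, row has {aa!r}"
                )
            out.append(cdna[3 * k : 3 * k + 3])
            k += 1
        rows_out.append("".join(out))
    return CodonAlignment(rows=(rows_out[0], rows_out[1]))
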