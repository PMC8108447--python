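# Methods

## Coordinate model and classification rules

All coordinates are 0-based half-open internally; GTF is converted on
read/write, BED passes through. Overlap between a transcript and a gene
model is the number of exonic base pairs shared with the gene's merged
exon union, counted strand-blind; orientation is a separate call. The
classification chain per transcript is:

1. **Support filter.** Keep transcripts with >= `min_fl` (default 2)
   full-length reads.
2. **Assignment.** The gene model with the greatest exonic-bp overlap
   wins; ties prefer pseudogene biotypes, then the lexicographically
   smallest gene id. Strict maximality makes the call deterministic.
3. **Retrocopy confirmation.** A pseudogene transcript is confirmed when
   >= 1 exonic bp intersects the retrocopy track, so hits to spliced
   "transcribed pseudogene" annotations that miss the retroposed copy
   itself do not count.
4. **Independence.** Independent iff the assigned pseudogene's overlap
   strictly exceeds the overlap with every non-pseudogene gene model, and
   the transcript is not intronic (entirely inside a gene's span with
   zero exon contact) within any non-pseudogene gene. Requiring *total*
   exon non-contact for intronic mirrors the "genic intron" category of
   long-read isoform classifiers.
5. **Orientation.** Sense iff the transcript strand equals the pseudogene
   record's strand. A retrocopy's annotated strand already encodes the
   parent-mRNA orientation at the insertion site, so no parent lookup is
   needed; strand "." is an error here. Antisense transcripts are
   classified by the same independence rule — the overlap clause compares
   against the pseudogene itself, which is orientation-free.
6. **Junction sharing.** A junction is the exact
   (chrom, donor end, acceptor start, strand) tuple of a consecutive exon
   pair; matching is exact to the base. Mono-exonic transcripts share
   nothing and are excluded from the sharing denominator (reported "n/a"
   when the denominator is empty).

Unprocessed pseudogenes flow through the same orientation call but skip
retrocopy confirmation (no retroposed interval exists for them).

## TSS and 3'-end evidence

The TSS is the first transcribed base (first exon start on '+', last exon
end − 1 on '−'). CAGE support is the distance from the TSS to the nearest
peak, boundary-inclusive at the window (default 100 bp, so exactly 100 bp
counts as supported). The CAGE meta-profile averages per-base signal in
bins (default 10 bp over ±500 bp), orienting windows 5'→3' by reversing
'−'-strand windows, with missing signal as 0 and per-bin means so
profiles are comparable across cohort sizes.

The polyA scan extracts the *genomic* (unspliced) window of 100 bases
ending at, and including, the 3'-terminal base, read in transcript
orientation. The canonical signal lies 10–40 nt upstream of the cleavage
site, so the window looks upstream; this choice of direction is a design
decision where the window's sidedness was genuinely open. AATAAA takes
precedence over ATTAAA when both occur; within a motif the occurrence
closest to the 3' end is reported, with the offset counted from the
terminal base to the motif's last base. Windows clipped at chromosome
edges are logged, not fatal.

## ORFs and fusions

An ORF is the longest ATG-initiated, stop-terminated frame on the
transcript strand; open-ended 3' frames are not called, ties go to the
5'-most start. `orf_at` measures the ORF from a fixed ATG without
downstream re-initiation, which is what the planted-frameshift recovery
test uses. Parent ORF length comes from annotated CDS intervals
(sum/3 − 1); the "intactness" statistic is the pure length ratio capped
at 1 — alignment-based intactness was considered and rejected because the
downstream summary is a length-fraction distribution.

A fusion is a transcript assigned to a protein-coding host gene whose
exons intersect a pseudogene retrocopy interval by >= 1 bp. Each ORF
codon is mapped through the exon chain to its three genomic positions; a
codon is pseudogene-derived when at least 2 of its 3 bases fall inside
the retrocopy (majority rule, so junction-straddling codons resolve
deterministically). The pseudogene's strand relative to the transcript is
reported, so antisense-derived fusions are detected — overlap and
orientation are assessed independently.

## Conservation analysis

Per transcript: extract the genomic span ±1000 bp (clipped at chromosome
ends, oriented to the transcript strand) from the second species; find
the orthologous cDNA by Smith–Waterman (match +2, mismatch −3, gap
open −5, extend −2, splice-naive; a gap of length k costs open +
extend·k). Because any shared base scores positively, a hit must reach
25% of the perfect-match score to count as an ortholog; windows in the
wrong orientation therefore correctly fail. The local alignment runs on
Biopython's C pairwise aligner with exactly this scoring model.

The located cDNA must be length-divisible by 3; terminal stops are
stripped, both copies translated, proteins aligned by Needleman–Wunsch
(BLOSUM62, affine open −11/extend −1, end gaps penalised, deterministic
traceback preferring diagonal > up > left), and the cDNAs threaded
through the protein alignment, gap columns becoming `---`.

NG86 counting: columns with gaps, ambiguous bases or stop codons are
excluded; mutations *to* stop count as nonsynonymous in the site
fractions; pathways through stop codons are excluded from the
multi-position averaging unless every pathway passes through one. The
Jukes–Cantor distance is undefined at p ≥ 3/4 and omega undefined when
dS = 0 or either distance is undefined. "Sufficient nucleotide
diversity" is operationalised as >= 1 observed difference with a defined,
nonzero dS; pairs failing it are reported `insufficient_diversity` and
excluded from the summary denominator. The summary reports the count and
fraction of omega < 1 (strict) and the median omega (midpoint for even
counts).

NG86-with-JC was chosen over a maximum-likelihood pairwise estimator
because it is exactly testable against brute-force enumeration (site
counts for all 61 sense codons; pathway averaging across all 61×61 codon
pairs) and agrees closely with ML at the low divergences involved
(primate-scale, roughly ≤ 25 My). The implementation is additionally
cross-checked in the tests against Biopython's independent NG86 routine.
The summary accepts any estimator producing (dN, dS).

`simulate_codon_divergence` evolves a CDS by Poisson(t·L) uniform
proposals, accepting synonymous changes always, nonsynonymous with
probability omega_true, and rejecting proposals that create stops. It
powers the parameter-recovery tests (estimated omega is monotone in
omega_true, and omega_true = 0 yields dN = 0 exactly) and the simulator's
ortholog generation.

## The simulator

The simulator is a pure function of (config, seed). It emulates:

- multi-exon protein-coding parent genes on '+' with ATG…stop CDSs
  (default 80–200 codons), 120 bp UTRs, GT…AG introns of 200–800 bp, in
  i.i.d. background sequence of GC ≈ 0.45, with 0.8–1.5 kb pads around
  features;
- retrotransposition: the spliced mRNA plus an 8–20 bp poly-A tract,
  inserted intergenically or intronically (default 15%) on a random
  strand, with tunable substitution divergence and indel rate. A planted
  frameshift (default fraction 0.3) is a single-base deletion at a codon
  boundary whose shifted frame is immediately truncated, so the disrupted
  ORF length equals the recorded CDS fraction exactly and recovery can be
  asserted without re-initiation slack;
- transcription: sense transcripts over each retrocopy, optional novel
  5' exons from an upstream promoter (default 50% of intergenic copies),
  antisense transcripts (default 35%), parent mRNAs, and fusion
  transcripts that splice a host gene's 5' exons (cut at a codon
  boundary, ~60% of the host CDS) onto the tail of a retrocopy CDS. The
  retro-derived tail is capped so the host keeps the greater overlap and
  the fusion is assigned to the host gene, as real gene–pseudogene
  fusions are;
- evidence: CAGE peaks of width 20 centred at every TSS with Gaussian
  jitter plus background peaks, a matching per-base bedGraph, and a
  canonical polyA motif implanted 10–40 nt upstream of each pseudogene
  transcript 3' end. The 100 bp 3' window is first cleared of incidental
  motifs (edits confined to UTR/poly-A/pad sequence, never CDS), so the
  planted call is the unique truth by construction;
- a second species: each pseudogene's ancestral mRNA independently
  re-diverged (CDS under the codon model at t = 0.08, roughly
  human–rhesus scale, omega_true = 0.45 — a purifying regime; UTRs at the
  neutral rate) and embedded in a 1 kb-flanked window, giving the
  conservation module realistic input without any genome download.

Read support is geometric (p = 0.45, minimum 1), so transcripts with a
single supporting read exist and exercise the support filter. Every
emitted transcript carries exactly one truth label (independent_sense,
independent_antisense, dependent_intronic, fusion, parent_mRNA) plus the
planted TSS, polyA call and fusion codon count.

What the simulator does **not** model: repeat families and segmental
duplication (so cross-mapping ambiguity is absent), splice-site sequence
realism beyond GT/AG, promoter sequence content (CAGE peaks are
positional only), sequencing error (the pipeline consumes transcript
models, not reads), expression-level biology of the counts, and
truncation artefacts of library preparation. Passing recovery tests
therefore demonstrates correctness of the *inference rules* on planted
structure, not robustness to alignment or annotation noise in real data.

## Problem sizes and defaults

The default cohort — 60 parent genes, 50 pseudogenes, 3 fusion sources,
~150 emitted transcripts (~80 past the support filter) on a ~270 kb
genome — is the scale at which every stage, including 50 Smith–Waterman
ortholog searches and NG86 estimates, completes in seconds; recovery
properties hold identically at several-fold larger configurations (the
frameshift-recovery test runs 200 pseudogenes). Percentages follow the
house style (one decimal below 10%, nearest integer otherwise, round
half up); stored counts stay exact. `counts_to_logcpm` is plain
log2(cpm + 1) with no between-sample normalisation — scaling-factor
normalisation (e.g. TMM) is deliberately out of scope. The qPCR
compartment enrichment is 2^(Ct_cyt − Ct_nuc) for nuclear (inverse for
cytoplasmic), on raw Ct values.

## Known limitations

- The overlap-based assignment approximates, but is not identical to,
  category assignment by long-read QC tools; edge cases near category
  boundaries may be flagged differently.
- The ortholog search is splice-naive local alignment; a terminal
  substitution in the ortholog can trim the aligned span and fail the
  divisible-by-3 gate (reported as such rather than silently rescued).
  Frameshifted copies fail the same gate, which is the intended
  behaviour.
- dN/dS is pairwise; no tree-based or branch-model estimation.
- Internal stop codons in a located ortholog abort the protein-alignment
  route (`no_orf`) rather than masking the offending codons.
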