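import itertools
import math
import warnings

import numpy as np
import pytest

from pseudotx.alignment import CodonAlignment
from pseudotx.conservation import (
    DnDsEstimate,
    _CODON_AA,
    check_divisible_by_three,
    codon_sites,
    dnds_summary,
    extract_flanked_window,
    ng86_dnds,
    pairwise_dnds,
    simulate_codon_divergence,
)
from pseudotx.genomic_io import GenomicInterval, TranscriptModel
from pseudotx.orfs import STOP_CODONS

SENSE_CODONS = [c for c, aa in _CODON_AA.items() if aa != "*"]


def oracle_site_count(codon):
    """Independent enumeration of all 9 single-base changes."""
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and _CODON_AA[alt] == _CODON_AA[codon]:
                syn += 1 / 3
    return syn


def oracle_pathway_average(c1, c2):
    """Average (syn, nonsyn) over orderings, by depth-first search."""
    diffs = [p for p in range(3) if c1[p] != c2[p]]

    def walk(cur, remaining):
        if not remaining:
            return [((0, 0), False)]
        out = []
        for p in remaining:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            step_stop = nxt in STOP_CODONS or cur in STOP_CODONS
            syn = (not step_stop) and _CODON_AA[nxt] == _CODON_AA[cur]
            for (s, n), hit in walk(nxt, [q for q in remaining if q != p]):
                out.append(((s + (1 if syn else 0), n + (0 if syn else 1)), hit or step_stop))
        return out

    paths = walk(c1, diffs)
    clean = [p for p in paths if not p[1]]
    pool = clean if clean else paths
    s = sum(p[0][0] for p in pool) / len(pool)
    n = sum(p[0][1] for p in pool) / len(pool)
    return s, n


class TestSiteCounts:
    def test_all_61_sense_codons_sum_to_three(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert s == pytest.approx(oracle_site_count(codon))

    def test_fourfold_degenerate_third_position(self):
        s, _ = codon_sites("GGA")
        assert s == pytest.approx(1.0)  # glycine: third position fully synonymous


class TestPathwayAveraging:
    def test_full_61x61_sweep_matches_enumeration_oracle(self):
        """NG86 difference counting agrees with brute-force ordering
        enumeration for every pair of sense codons (<= 3 differences)."""
        from pseudotx.conservation import _pathway_counts

        for c1, c2 in itertools.product(SENSE_CODONS, SENSE_CODONS):
            got = _pathway_counts(c1, c2)
            exp = oracle_pathway_average(c1, c2)
            assert got[0] == pytest.approx(exp[0]), (c1, c2)
            assert got[1] == pytest.approx(exp[1]), (c1, c2)


class TestNg86WorkedExamples:
    def test_identical_sequences(self):
        est = ng86_dnds(CodonAlignment(rows=("ATGGAT", "ATGGAT")))
        assert est.Sd == est.Nd == 0 and est.dS == est.dN == 0
        assert est.omega is None and est.status == "insufficient_diversity"

    def test_single_nonsynonymous_difference(self):
        est = ng86_dnds(CodonAlignment(rows=("ATGGAT", "ATGGAA")))
        assert (est.Sd, est.Nd) == (0, 1)
        assert est.pS == 0 and est.dS == 0
        assert est.omega is None

    def test_single_synonymous_difference(self):
        est = ng86_dnds(CodonAlignment(rows=("ATGGGAAAATTT", "ATGGGGAAATTT")))
        assert (est.Sd, est.Nd) == (1, 0)
        assert est.S == pytest.approx(5 / 3)
        assert est.pN == 0 and est.dN == 0 and est.omega == 0.0

    def test_gap_and_ambiguous_columns_excluded(self):
        est = ng86_dnds(CodonAlignment(rows=("ATG---GAN", "ATGGGAGAA")))
        assert est.n_codons == 1  # only the ATG column is usable

    def test_no_usable_columns_rejected(self):
        with pytest.raises(ValueError):
            ng86_dnds(CodonAlignment(rows=("---", "GGG")))

    def test_jukes_cantor_undefined_at_saturation(self):
        # leucine pairs where every difference is synonymous: pS = 2/(S=...)
        est = ng86_dnds(CodonAlignment(rows=("TTA", "CTG")))
        assert est.Sd == 2 and est.dS is None and est.omega is None

    def test_matches_biopython_ng86(self):
        from pseudotx.simulate import _random_cds

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(7)
        cds = _random_cds(rng, 150)[:-3]
        diverged = simulate_codon_divergence(cds, 0.15, 0.8, 42)
        est = ng86_dnds(CodonAlignment(rows=(cds, diverged)))
        dn, ds = cal_dn_ds(CodonSeq(cds), CodonSeq(diverged), method="NG86")
        assert est.dN == pytest.approx(dn, abs=1e-9)
        assert est.dS == pytest.approx(ds, abs=1e-9)


class TestSummary:
    def test_counts_and_median(self):
        ests = [
            DnDsEstimate(1, 2, 1, 1, 0.1, 0.1, 0.1, o * 0.1, o, n_diffs=2)
            for o in (0.2, 0.5, 1.5)
        ]
        n, pur, frac, med = dnds_summary(ests)
        assert (n, pur) == (3, 2) and frac == pytest.approx(2 / 3) and med == 0.5

    def test_all_undefined(self):
        est = DnDsEstimate(1, 2, 0, 0, 0, 0, 0.0, 0.0, None)
        assert dnds_summary([est]) == (0, 0, None, None)

    def test_even_count_median_is_midpoint(self):
        ests = [DnDsEstimate(1, 2, 1, 1, 0.1, 0.1, 0.1, 0.1, o, n_diffs=2) for o in (0.2, 0.6)]
        assert dnds_summary(ests)[3] == pytest.approx(0.4)


class TestFlankedWindow:
    def test_flank_size(self):
        genome = {"chr1": "A" * 5000}
        tx = TranscriptModel(id="t", exons=[GenomicInterval("chr1", 1000, 2000, "+")])
        assert len(extract_flanked_window(tx, genome, flank=1000)) == 3000

    def test_clipped_at_chromosome_start(self):
        genome = {"chr1": "A" * 5000}
        tx = TranscriptModel(id="t", exons=[GenomicInterval("chr1", 100, 600, "+")])
        assert len(extract_flanked_window(tx, genome, flank=1000)) == 100 + 500 + 1000

    def test_zero_flank_is_genomic_span(self):
        genome = {"chr1": "ACGTACGTAC" * 10}
        tx = TranscriptModel(id="t", exons=[GenomicInterval("chr1", 8, 24, "+")])
        assert extract_flanked_window(tx, genome, flank=0) == genome["chr1"][8:24]

    def test_minus_strand_orientation(self):
        from Bio.Seq import Seq

        genome = {"chr1": "AACCGGTTAACCGGTT"}
        tx = TranscriptModel(id="t", exons=[GenomicInterval("chr1", 4, 12, "-")])
        assert extract_flanked_window(tx, genome, flank=2) == str(
            Seq(genome["chr1"][2:14]).reverse_complement()
        )


class TestDivisibleByThree:
    @pytest.mark.parametrize("n,ok", [(9, True), (10, False), (0, True)])
    def test_lengths(self, n, ok):
        assert check_divisible_by_three("A" * n) is ok


class TestDivergenceSimulator:
    def test_zero_time_is_identity(self):
        cds = "ATGGATGAAACC"
        assert simulate_codon_divergence(cds, 0.0, 0.5, 1) == cds

    def test_omega_zero_preserves_protein(self):
        from pseudotx.orfs import translate
        from pseudotx.simulate import _random_cds

        rng = np.random.default_rng(3)
        cds = _random_cds(rng, 120)[:-3]
        out = simulate_codon_divergence(cds, 0.5, 0.0, 11)
        assert translate(out) == translate(cds)
        assert out != cds  # synonymous changes did accumulate

    def test_deterministic_under_seed(self):
        cds = "ATG" + "GCT" * 50
        assert simulate_codon_divergence(cds, 0.3, 0.5, 5) == simulate_codon_divergence(cds, 0.3, 0.5, 5)

    def test_neutral_divergence_equalises_rates(self):
        """omega_true = 1 gives pN ~ pS under NG86 across replicates."""
        from pseudotx.simulate import _random_cds

        rng = np.random.default_rng(9)
        ratios = []
        for rep in range(30):
            cds = _random_cds(rng, 200)[:-3]
            d = simulate_codon_divergence(cds, 0.4, 1.0, 1000 + rep)
            est = ng86_dnds(CodonAlignment(rows=(cds, d)))
            if est.omega is not None:
                ratios.append(est.omega)
        assert np.median(ratios) == pytest.approx(1.0, abs=0.15)


class TestPairwisePipeline:
    def test_verbatim_copy_has_insufficient_diversity(self):
        from pseudotx.simulate import _random_cds

        rng = np.random.default_rng(5)
        cdna = _random_cds(rng, 100)
        window = "C" * 500 + cdna + "C" * 500
        est, status = pairwise_dnds(cdna, window)
        assert status == "insufficient_diversity"
        assert est is not None and est.n_diffs == 0

    def test_diverged_ortholog_recovers_purifying_omega(self):
        from pseudotx.simulate import _random_cds

        rng = np.random.default_rng(6)
        cdna = _random_cds(rng, 200)
        body, stop = cdna[:-3], cdna[-3:]
        evolved = simulate_codon_divergence(body, 0.15, 0.2, 77) + stop
        window = "C" * 300 + evolved + "C" * 300
        est, status = pairwise_dnds(cdna, window)
        assert status == "defined"
        assert est.omega is not None and est.omega < 1.0

    def test_frameshifted_cdna_rejected(self):
        cdna = "ATGGATGA"  # length 8
        window = "C" * 50 + cdna + "C" * 50
        est, status = pairwise_dnds(cdna, window)
        assert est is None and status == "not_divisible_by_3"
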