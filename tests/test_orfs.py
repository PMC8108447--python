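import re

import pytest
from hypothesis import given, settings, strategies as st

from pseudotx.classifier import ClassifiedTranscript
from pseudotx.genomic_io import (
    Biotype,
    GeneModel,
    GenomicInterval,
    PseudogeneRecord,
    TranscriptModel,
)
from pseudotx.orfs import (
    STOP_CODONS,
    codon_genomic_positions,
    detect_fusions,
    find_longest_orf,
    orf_at,
    orf_exceeds,
    parent_orf_fraction,
    translate,
)


class TestTranslate:
    @pytest.mark.parametrize(
        "cdna,protein", [("ATGTAA", "M*"), ("ATGGATGAA", "MDE"), ("ATGNNNTAA", "MX*")]
    )
    def test_examples(self, cdna, protein):
        assert translate(cdna) == protein

    def test_length_not_divisible_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGGA")


def brute_force_longest_orf(seq):
    """Independent oracle: enumerate every ATG..stop span via regex scan."""
    best = None
    for m in re.finditer("ATG", seq):
        start = m.start()
        for i in range(start + 3, len(seq) - 2, 3):
            if seq[i : i + 3] in STOP_CODONS:
                aa = (i - start) // 3
                if best is None or aa > best[0] or (aa == best[0] and start < best[1]):
                    best = (aa, start, i + 3)
                break
    return best


class TestFindLongestOrf:
    def test_no_atg(self):
        assert find_longest_orf("CCCCCCTAA") is None

    def test_hand_scanned_example(self):
        orf = find_longest_orf("AAATGGCCTAACCC")
        assert orf.protein == "MA" and orf.aa_length == 2 and orf.start_nt == 2

    def test_tie_returns_five_prime_most(self):
        # two 1-aa ORFs in different frames; starts at 0 and 7
        seq = "ATGTAAGATGTAG"
        orf = find_longest_orf(seq)
        assert orf.start_nt == 0

    def test_stop_required(self):
        assert find_longest_orf("ATGGCCGCC") is None

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_agrees_with_brute_force(self, seq):
        expected = brute_force_longest_orf(seq)
        got = find_longest_orf(seq)
        if expected is None:
            assert got is None
        else:
            assert (got.aa_length, got.start_nt, got.end_nt) == expected

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=9, max_size=60))
    def test_orf_translates_cleanly(self, seq):
        orf = find_longest_orf(seq)
        if orf is None:
            return
        prot = translate(seq[orf.start_nt : orf.end_nt])
        assert prot == orf.protein + "*"
        assert "*" not in orf.protein


class TestOrfThresholds:
    def test_strict_boundary(self):
        orf100 = find_longest_orf("ATG" + "GCC" * 100 + "TAA")
        orf101 = find_longest_orf("ATG" + "GCC" * 101 + "TAA")
        assert orf100.aa_length == 101  # M + 100 Ala
        assert orf_exceeds(orf100, 100) and not orf_exceeds(orf100, 101)
        assert orf_exceeds(orf101, 101)

    def test_none_orf(self):
        assert not orf_exceeds(None, 100)


class TestParentFraction:
    def test_equal_length(self):
        orf = find_longest_orf("ATG" + "GCC" * 89 + "TAA")
        assert parent_orf_fraction(orf, 90) == 1.0

    def test_half(self):
        orf = find_longest_orf("ATG" + "GCC" * 44 + "TAA")
        assert parent_orf_fraction(orf, 90) == 0.5

    def test_capped_at_one(self):
        orf = find_longest_orf("ATG" + "GCC" * 119 + "TAA")
        assert parent_orf_fraction(orf, 100) == 1.0

    def test_no_orf_is_zero(self):
        assert parent_orf_fraction(None, 90) == 0.0

    def test_zero_parent_rejected(self):
        with pytest.raises(ValueError):
            parent_orf_fraction(None, 0)


class TestOrfAt:
    def test_truncates_at_first_stop(self):
        seq = "ATGGCCTAAATGGCCGCCGCCTAA"  # 2-aa ORF then a longer downstream one
        orf = orf_at(seq, 0)
        assert orf.aa_length == 2
        assert find_longest_orf(seq).aa_length == 4

    def test_requires_atg(self):
        assert orf_at("CCCGCCTAA", 0) is None


class TestFusionAccounting:
    def _fixture(self):
        """60-codon ORF; last 20 codons (and the stop) in a retro interval."""
        cds = "ATG" + "GCA" * 59 + "TAA"
        utr5, utr3 = "C" * 50, "G" * 50
        seq = utr5 + cds + utr3
        genome = {"chr1": seq}
        tx = TranscriptModel(
            id="fx", exons=[GenomicInterval("chr1", 0, len(seq), "+")], fl_read_count=5
        )
        host = GeneModel(
            id="HOST", name="HOST", biotype=Biotype.protein_coding,
            transcripts=[TranscriptModel(id="HOST.t1", exons=[GenomicInterval("chr1", 0, len(seq), "+")])],
        )
        retro_start = 50 + 40 * 3  # from codon 40 onward
        pg_gene = GeneModel(
            id="PSG", name="PSG", biotype=Biotype.processed_pseudogene,
            transcripts=[TranscriptModel(id="PSG.t1", exons=[GenomicInterval("chr1", retro_start, len(seq), "+")])],
        )
        rec = PseudogeneRecord(
            gene=pg_gene, parent_gene_id="P",
            retro_interval=GenomicInterval("chr1", retro_start, len(seq), "+"),
        )
        ct = ClassifiedTranscript(
            tx=tx, assigned_gene_id="HOST", assignment_overlap_bp=len(seq),
            is_pseudogene_transcript=False,
        )
        return ct, [host, pg_gene], {"PSG": rec}, genome

    def test_codons_from_pseudogene(self):
        ct, genes, recs, genome = self._fixture()
        (fusion,) = detect_fusions([ct], genes, recs, genome)
        assert fusion.codons_from_pseudogene == 20
        assert fusion.host_gene_id == "HOST"
        assert fusion.pseudogene_strand_relative.value == "sense"

    def test_no_overlap_no_record(self):
        ct, genes, recs, genome = self._fixture()
        recs["PSG"].retro_interval = GenomicInterval("chr2", 0, 100, "+")
        recs["PSG"].gene.transcripts[0].exons = [GenomicInterval("chr2", 0, 100, "+")]
        assert detect_fusions([ct], genes, recs, genome) == []

    def test_straddling_codon_majority_rule(self):
        """A codon with 2 of 3 bases inside the interval counts; 1 of 3 does not."""
        ct, genes, recs, genome = self._fixture()
        # shift the interval 1 bp into codon 40: codon 40 keeps 2/3 bases inside
        start = 50 + 40 * 3 + 1
        recs["PSG"].retro_interval = GenomicInterval("chr1", start, len(genome["chr1"]), "+")
        (fusion,) = detect_fusions([ct], genes, recs, genome)
        assert fusion.codons_from_pseudogene == 20
        # shift 2 bp in: codon 40 has only 1/3 inside and drops out
        recs["PSG"].retro_interval = GenomicInterval("chr1", start + 1, len(genome["chr1"]), "+")
        (fusion,) = detect_fusions([ct], genes, recs, genome)
        assert fusion.codons_from_pseudogene == 19

    def test_missing_genome_rejected(self):
        ct, genes, recs, _ = self._fixture()
        with pytest.raises(ValueError):
            detect_fusions([ct], genes, recs, {})


class TestCodonMapping:
    def test_minus_strand_positions_descend(self):
        seq = "TTA" + "GGC" * 4 + "CAT"  # revcomp: ATG GCC GCC GCC GCC TAA
        tx = TranscriptModel(id="t", exons=[GenomicInterval("chr1", 0, len(seq), "-")])
        orf = find_longest_orf("ATG" + "GCC" * 4 + "TAA")
        pos = codon_genomic_positions(tx, orf)
        assert pos[0] == (17, 16, 15)  # first codon maps to the chromosome end
        assert len(pos) == 5  # stop codon excluded
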