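import hashlib

import numpy as np
import pytest

from pseudotx.genomic_io import read_bed, read_bedgraph, read_fasta, read_gtf
from pseudotx.orfs import find_longest_orf, orf_at, parent_orf_fraction
from pseudotx.simulate import (
    SimulationConfig,
    emit,
    make_parent_gene,
    retropose,
    simulate,
)


class TestParentGene:
    def test_requested_exon_count(self):
        cfg = SimulationConfig(exons_per_gene=(3, 3))
        rng = np.random.default_rng(0)
        g = make_parent_gene(cfg, rng)
        assert len(g.exon_seqs) == 3

    def test_cds_translates_without_internal_stops(self):
        from pseudotx.orfs import translate

        cfg = SimulationConfig(cds_length_codons=(100, 100))
        g = make_parent_gene(cfg, np.random.default_rng(1))
        cds = g.mrna[g.utr : len(g.mrna) - g.utr]
        prot = translate(cds)
        assert len(prot) == 101 and prot.endswith("*") and "*" not in prot[:-1]

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig()
        a = make_parent_gene(cfg, np.random.default_rng(5))
        b = make_parent_gene(cfg, np.random.default_rng(5))
        assert a.seq == b.seq and a.mrna == b.mrna


class TestRetropose:
    def _retro(self, **kw):
        cfg = kw.pop("cfg", SimulationConfig())
        rng = np.random.default_rng(kw.pop("seed", 2))
        parent = make_parent_gene(cfg, rng)
        return parent, retropose(
            parent, cfg, rng, pseudo_id="P0", placement="intergenic",
            frameshift=kw.pop("frameshift", False), **kw,
        )

    def test_zero_divergence_copies_mrna_exactly(self):
        parent, r = self._retro()
        assert r.seq.startswith(parent.mrna)
        assert set(r.seq[len(parent.mrna):]) == {"A"}  # poly-A tract
        assert 8 <= len(r.seq) - len(parent.mrna) <= 20

    def test_frameshift_truncates_orf_at_recorded_fraction(self):
        parent, r = self._retro(frameshift=True)
        orf = orf_at(r.seq, r.cds_start)
        frac = parent_orf_fraction(orf, parent.cds_codons)
        assert frac <= r.frameshift_fraction + 1e-9
        assert frac == pytest.approx(
            int(r.frameshift_fraction * parent.cds_codons) / parent.cds_codons
        )

    def test_divergence_perturbs_sequence(self):
        cfg = SimulationConfig(divergence=0.05)
        parent, r = self._retro(cfg=cfg)
        mism = sum(1 for a, b in zip(parent.mrna, r.seq) if a != b)
        assert 0 < mism < 0.15 * len(parent.mrna)


class TestEndToEndProperties:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_parent_genes=8, n_pseudogenes=5, fusion_count=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = emit(simulate(cfg), d1)
        p2 = emit(simulate(SimulationConfig(**{**cfg.__dict__})), d2)
        for key in p1:
            h1 = hashlib.sha256(p1[key].read_bytes()).hexdigest()
            h2 = hashlib.sha256(p2[key].read_bytes()).hexdigest()
            assert h1 == h2, key

    def test_outputs_parse_back_losslessly(self, tmp_path):
        cfg = SimulationConfig(seed=12, n_parent_genes=6, n_pseudogenes=4, fusion_count=1)
        sim = simulate(cfg)
        paths = emit(sim, tmp_path)
        genome = read_fasta(paths["genome"])
        assert genome == sim.genome
        txs = read_bed(paths["transcripts"], blocked=True)
        assert {t.id for t in txs} == {t.id for t in sim.transcripts}
        by_id = {t.id: t for t in sim.transcripts}
        for t in txs:
            assert [(e.start, e.end) for e in t.exons] == [
                (e.start, e.end) for e in by_id[t.id].exons
            ]
        genes = read_gtf(paths["annotation"])
        assert {g.id for g in genes} == {g.id for g in sim.genes}
        signal = read_bedgraph(paths["cage_signal"])
        assert signal == sim.cage_signal

    def test_no_pseudogenes_means_no_pseudogene_transcripts(self):
        from pseudotx import run_cohort

        cfg = SimulationConfig(seed=13, n_parent_genes=6, n_pseudogenes=0, fusion_count=0)
        sim = simulate(cfg)
        res = run_cohort(
            sim.transcripts, sim.genes, sim.pseudogene_records, sim.genome, sim.cage_peaks
        )
        assert not any(c.is_pseudogene_transcript for c in res.classified)

    def test_planted_frameshift_fraction_recovered_by_orf_stage(self):
        """Pseudogenes with a planted frameshift lose >10% of the parent ORF;
        intact ones keep it all, so the <0.9 fraction estimates the planted rate."""
        cfg = SimulationConfig(
            seed=21, n_parent_genes=210, n_pseudogenes=200, fusion_count=0,
            antisense_fraction=0.0, novel_five_prime_exon_fraction=0.0,
            frameshift_fraction=0.3,
        )
        sim = simulate(cfg)
        truth_fs = {p.pseudogene_id: p.frameshift for p in sim.truth.pseudogenes}
        parent_aa = {p.pseudogene_id: p.parent_orf_aa for p in sim.truth.pseudogenes}
        n_disrupted = 0
        sense = [t for t in sim.transcripts if t.id.startswith("tx_sense_")]
        for t in sense:
            pid = t.id.removeprefix("tx_sense_")
            orf = find_longest_orf(t.spliced_sequence(sim.genome))
            if parent_orf_fraction(orf, parent_aa[pid]) < 0.9:
                n_disrupted += 1
        observed = n_disrupted / len(sense)
        expected = sum(truth_fs.values()) / len(truth_fs)
        assert observed == pytest.approx(expected, abs=0.05)

    def test_cage_jitter_degrades_support_monotonically(self):
        from pseudotx.features import cage_support
        from pseudotx.intervals import IntervalSet

        rates = []
        for sd in (0.0, 300.0):
            cfg = SimulationConfig(
                seed=31, n_parent_genes=10, n_pseudogenes=8,
                fusion_count=0, cage_jitter_sd=sd, cage_background_peaks=0,
            )
            sim = simulate(cfg)
            peaks = IntervalSet(list(sim.cage_peaks))
            hits = [
                cage_support(t.tss, peaks).supported for t in sim.truth.transcripts
            ]
            rates.append(sum(hits) / len(hits))
        assert rates[0] == 1.0  # jitter 0: every TSS supported
        assert rates[1] < rates[0]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(antisense_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(polya_motif_offset=(5, 40)).validate()
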