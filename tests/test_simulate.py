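import numpy as np
import pytest

from editcall import (
    ErrorModel,
    add_paralog_decoy,
    make_reference,
    misaligned_copy,
    plant_sites,
    simulate_dna_reads,
    simulate_reads,
)
from editcall.io import read_sam, write_sam


class TestMakeReference:
    def test_same_seed_reproduces_genome_and_models(self):
        g1, m1 = make_reference(seed=7)
        g2, m2 = make_reference(seed=7)
        assert g1["chr_sim"].seq == g2["chr_sim"].seq
        assert m1 == m2

    def test_strands_alternate(self):
        _, models = make_reference(seed=1, n_genes=4)
        assert [m.strand for m in models].count("+") == 2

    def test_gene_span_is_sum_of_exons_and_introns(self):
        _, models = make_reference(seed=1, exons_per_gene=3, exon_len=150, intron_len=100)
        for m in models:
            assert m.end - m.start + 1 == 3 * 150 + 2 * 100
            assert m.transcript_length == 450
            assert m.cds_length() % 3 == 0

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_reference(seed=1, exons_per_gene=1, exon_len=50, utr5_len=30, utr3_len=30)


class TestPlantSites:
    def test_editing_planted_on_transcribed_strand_adenosines(self, sim_truth):
        assert len(sim_truth.editing_sites) == 5
        for e in sim_truth.editing_sites:
            genomic_base = sim_truth.genome[e.chrom].base(e.position)
            assert genomic_base == ("A" if e.strand == "+" else "T")
            assert e.level == 0.4

    def test_minus_strand_sites_exist_and_are_genomic_t(self):
        genome, models = make_reference(seed=2)
        truth = plant_sites(genome, models, n_editing=12, levels=0.3, seed=2)
        minus = [e for e in truth.editing_sites if e.strand == "-"]
        assert minus, "expected sites on minus-strand genes"
        for e in minus:
            assert genome[e.chrom].base(e.position) == "T"

    def test_editing_and_snp_positions_disjoint(self, sim_truth):
        edit = sim_truth.editing_positions()
        snp = {(s.chrom, s.position) for s in sim_truth.snps}
        assert edit.isdisjoint(snp)

    def test_requesting_too_many_sites_fails(self):
        genome, models = make_reference(seed=1, n_genes=2)
        with pytest.raises(ValueError, match="eligible"):
            plant_sites(genome, models, n_editing=10_000, levels=0.5, seed=1)


class TestSimulateReads:
    def test_same_seed_gives_identical_reads(self, sim_truth):
        r1 = simulate_reads(sim_truth, mean_coverage=20, read_len=50, seed=4)
        r2 = simulate_reads(sim_truth, mean_coverage=20, read_len=50, seed=4)
        assert r1 == r2

    def test_alt_fraction_near_planted_level(self):
        genome, models = make_reference(seed=9)
        truth = plant_sites(genome, models, n_editing=3, levels=0.4,
                            n_het_snps=0, n_hom_snps=0, seed=9)
        reads = simulate_reads(truth, mean_coverage=200, read_len=50, seed=10)
        from editcall import pileup_alignments

        sites = {(s.chrom, s.position): s
                 for s in pileup_alignments(reads, genome, min_quality=0)}
        for e in truth.editing_sites:
            sc = sites[(e.chrom, e.position)]
            alt = "G" if e.strand == "+" else "C"
            n_alt = sc.count(alt, filtered=False)
            n = sc.raw_coverage
            sd = np.sqrt(0.4 * 0.6 * n)
            assert abs(n_alt - 0.4 * n) <= 3 * sd

    def test_error_rate_matches_phred_calibration(self):
        genome, models = make_reference(seed=13)
        truth = plant_sites(genome, models, n_editing=0, levels=[],
                            n_het_snps=0, n_hom_snps=0, seed=13,
                            error_model=ErrorModel(phred=30))
        reads = simulate_reads(truth, mean_coverage=50, read_len=50, seed=14)
        mismatches = total = 0
        for rec in reads:
            offset = 0
            for s, e in rec.blocks:
                ref = genome[rec.ref_name].seq[s - 1 : e]
                seg = rec.bases[offset : offset + e - s + 1]
                mismatches += sum(a != b for a, b in zip(seg, ref))
                total += len(seg)
                offset += e - s + 1
        sd = np.sqrt(1e-3 * (1 - 1e-3) * total)
        assert abs(mismatches - 1e-3 * total) <= 3 * sd

    def test_stranded_reads_follow_gene_strand(self, sim_truth):
        by_tx = {m.transcript_id: m for m in sim_truth.models}
        reads = simulate_reads(sim_truth, mean_coverage=10, read_len=50,
                               stranded=True, seed=5)
        for rec in reads:
            model = by_tx[rec.read_id.split("|")[0]]
            assert rec.strand == model.strand

    def test_paired_reads_come_in_proper_mates(self, sim_truth):
        reads = simulate_reads(sim_truth, mean_coverage=10, read_len=50,
                               paired=True, seed=6)
        mates = {}
        for rec in reads:
            assert rec.paired
            mates.setdefault(rec.read_id, set()).add(rec.mate)
        assert all(v == {1, 2} for v in mates.values())

    def test_round_trips_through_sam(self, sim_truth, tmp_path):
        reads = simulate_reads(sim_truth, mean_coverage=5, read_len=50, seed=7)
        lengths = {c: len(g) for c, g in sim_truth.genome.items()}
        path = tmp_path / "reads.sam"
        write_sam(reads, path, lengths)
        assert read_sam(path) == reads


class TestSimulateDnaReads:
    def test_determinism(self, sim_truth):
        d1 = simulate_dna_reads(sim_truth, mean_coverage=10, seed=8)
        d2 = simulate_dna_reads(sim_truth, mean_coverage=10, seed=8)
        assert d1 == d2

    def test_editing_invisible_in_dna(self):
        genome, models = make_reference(seed=17)
        truth = plant_sites(genome, models, n_editing=3, levels=1.0,
                            n_het_snps=0, n_hom_snps=0, seed=17)
        dna = simulate_dna_reads(truth, mean_coverage=100, seed=18)
        from editcall import pileup_alignments

        sites = {(s.chrom, s.position): s
                 for s in pileup_alignments(dna, genome, min_quality=0)}
        for e in truth.editing_sites:
            sc = sites[(e.chrom, e.position)]
            alt = "G" if e.strand == "+" else "C"
            # alternate bases only from sequencing error (~1e-3/3 per base)
            assert sc.count(alt, filtered=False) <= 3

    def test_het_snp_allele_fraction_near_half(self):
        genome, models = make_reference(seed=19)
        truth = plant_sites(genome, models, n_editing=0, levels=[],
                            n_het_snps=3, n_hom_snps=1, seed=19)
        dna = simulate_dna_reads(truth, mean_coverage=100, seed=20)
        from editcall import pileup_alignments

        sites = {(s.chrom, s.position): s
                 for s in pileup_alignments(dna, genome, min_quality=0)}
        for s in truth.snps:
            sc = sites[(s.chrom, s.position)]
            n_alt = sc.count(s.alt, filtered=False)
            n = sc.raw_coverage
            frac = 0.5 if s.genotype == "het" else 1.0
            sd = np.sqrt(max(frac * (1 - frac), 0.01) * n)
            assert abs(n_alt - frac * n) <= 3 * sd + 1


class TestParalogDecoy:
    def test_decoy_is_intronless_copy_with_a_for_g_mismatches(self):
        genome, models = make_reference(seed=23)
        new_genome, new_models, decoy = add_paralog_decoy(
            genome, models, source_index=0, n_mismatches=3, seed=23
        )
        decoy_model = new_models[-1]
        assert len(decoy_model.exons) == 1
        source = models[0]
        cdna = source.transcript_seq(genome)
        copy = new_genome[decoy.chrom].seq[decoy.start - 1 : decoy.end]
        diffs = [i for i, (a, b) in enumerate(zip(cdna, copy)) if a != b]
        assert len(diffs) == 3
        for i in diffs:
            assert cdna[i] == "G" and copy[i] == "A"
        assert decoy.mismatch_positions == tuple(decoy.start + i for i in diffs)

    def test_misaligned_copy_relocates_only_source_gene_reads(self):
        genome, models = make_reference(seed=23)
        new_genome, new_models, decoy = add_paralog_decoy(genome, models, seed=23)
        truth = plant_sites(new_genome, models, n_editing=2, levels=0.4, seed=23)
        truth.models = new_models
        reads = simulate_reads(truth, mean_coverage=30, read_len=50, seed=24)
        moved = misaligned_copy(reads, new_models, decoy, fraction=1.0, seed=25)
        for orig, new in zip(reads, moved):
            if orig.read_id.split("|")[0] == decoy.source_transcript_id:
                assert len(new.blocks) == 1
                assert decoy.start <= new.start <= decoy.end
            else:
                assert new == orig
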