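"""Generators: determinism, truth-table consistency, model calibration."""
import math

import numpy as np
import pytest

from oopromscan.io_formats import GenomicSequence, parse_newick
from oopromscan.synthetic_data import (IsoformMixSpec, MotifPlantSpec, TESimSpec,
                                       default_splice_gene, evolve_alignment,
                                       mutate_codons, promoter_screen_scenario,
                                       sample_hmm_columns, simulate_spliced_reads,
                                       simulate_te_counts)
from oopromscan.conservation_hmm import HmmParams
from oopromscan.isoform_splice import extract_junctions

BLOCK = "TTCTTAA" + "CT" * 12 + "C" + "A" + "GAGAGAGAGA"


class TestEvolveAlignment:
    def test_seed_mandatory(self):
        tree = parse_newick("(a:1,b:1);")
        anc = GenomicSequence(id="x", residues="ACGT" * 20)
        with pytest.raises(ValueError, match="seed"):
            evolve_alignment(tree, anc, 0.1, 0.0, None, seed=None)

    def test_zero_rate_plant(self):
        tree = parse_newick("((m:1,r:1):1,h:1);")
        anc = GenomicSequence(id="x", residues="G" * 50)
        plant = MotifPlantSpec(clade_leaves={"m", "r"}, motif="TTCTTAA",
                               offset_in_ancestor=10)
        aln, truth = evolve_alignment(tree, anc, 0.0, 0.0, plant, seed=1)
        for sp in ("m", "r"):
            assert aln.ungapped(sp).residues[10:17] == "TTCTTAA"
            assert truth["status"][sp] == "present"
            assert truth["motif_start"][sp] == 10
        assert "TTCTTAA" not in aln.ungapped("h").residues
        assert truth["status"]["h"] == "absent"

    def test_deletion_leaf_gapped(self):
        tree = parse_newick("((m:1,r:1,v:1):1,h:1);")
        anc = GenomicSequence(id="x", residues="G" * 60)
        plant = MotifPlantSpec(clade_leaves={"m", "r", "v"}, motif="TTCTTAA",
                               offset_in_ancestor=20, deletion_leaf="v",
                               deletion_window=(15, 20))
        aln, truth = evolve_alignment(tree, anc, 0.0, 0.0, plant, seed=1)
        assert truth["status"]["v"] == "region_deleted"
        # the deleted window is all gaps in v
        row = aln.rows["v"]
        assert set(row[15:35]) == {"-"}

    def test_jukes_cantor_fraction(self):
        tree = parse_newick("(a:1,b:0.000001);")
        rng_anc = GenomicSequence(id="x", residues="ACGT" * 2500)
        aln, _ = evolve_alignment(tree, rng_anc, 0.1, 0.0, None, seed=4)
        a = aln.ungapped("a").residues
        expected_p = 0.75 * (1 - math.exp(-4 * 0.1 / 3))
        observed = sum(1 for x, y in zip(a, rng_anc.residues) if x != y) / len(a)
        se = math.sqrt(expected_p * (1 - expected_p) / len(a))
        assert abs(observed - expected_p) <= 3 * se

    def test_byte_level_determinism(self):
        sc1 = promoter_screen_scenario(3, n_species=8, ancestor_len=600)
        sc2 = promoter_screen_scenario(3, n_species=8, ancestor_len=600)
        assert sc1["alignment"].rows == sc2["alignment"].rows
        assert sc1["truth"] == sc2["truth"]

    def test_truth_present_species_carry_exact_motif(self):
        sc = promoter_screen_scenario(5, n_species=10, ancestor_len=1000)
        aln, truth = sc["alignment"], sc["truth"]
        for sp, status in truth["status"].items():
            if status == "present":
                start = truth["motif_start"][sp]
                assert aln.ungapped(sp).residues[start : start + len(BLOCK)] == BLOCK


class TestSimulateSplicedReads:
    def test_total_records_and_cigar_consistency(self):
        gene = default_splice_gene()
        recs, truth = simulate_spliced_reads(IsoformMixSpec(
            gene=gene, exclusion_fraction=0.4, n_reads=500, seed=2))
        assert len(recs) == 500 == truth["n_reads"]
        exon_bounds = {b for exon in gene.exons for b in exon}
        for r in recs:
            for j in extract_junctions(r):
                assert j.donor_end in exon_bounds and j.acceptor_start in exon_bounds

    def test_exclusion_fraction_extremes(self):
        gene = default_splice_gene()
        recs0, truth0 = simulate_spliced_reads(IsoformMixSpec(
            gene=gene, exclusion_fraction=0.0, n_reads=500, seed=3))
        assert truth0["n_exclusion_spanning"] == 0
        recs1, truth1 = simulate_spliced_reads(IsoformMixSpec(
            gene=gene, exclusion_fraction=1.0, n_reads=500, seed=3))
        assert truth1["n_inclusion_spanning"] == 0
        assert truth1["n_skip_isoform_reads"] == 500

    def test_read_length_validation(self):
        gene = default_splice_gene()
        with pytest.raises(ValueError, match="read_length"):
            simulate_spliced_reads(IsoformMixSpec(gene=gene, read_length=500, seed=1))

    def test_determinism(self):
        gene = default_splice_gene()
        spec = IsoformMixSpec(gene=gene, n_reads=200, seed=9)
        r1, t1 = simulate_spliced_reads(spec)
        r2, t2 = simulate_spliced_reads(spec)
        assert r1 == r2 and t1 == t2


class TestSimulateTeCounts:
    def test_determinism(self):
        spec = TESimSpec(seed=6)
        i1, t1, truth1 = simulate_te_counts(spec)
        i2, t2, truth2 = simulate_te_counts(spec)
        assert i1 == i2
        assert t1.counts.equals(t2.counts)
        assert truth1.equals(truth2)

    def test_all_genic_means_no_eligible(self):
        _, _, truth = simulate_te_counts(TESimSpec(genic_fraction=1.0, seed=7))
        assert (truth["eligible_insertions"] == 0).all()

    def test_fold_change_shifts_counts(self):
        spec = TESimSpec(n_subfamilies=2, insertions_per_subfamily=200,
                         fold_changes=[1.0, 4.0], mean_count=50, seed=8)
        _, table, _ = simulate_te_counts(spec)
        sf1 = table.counts.loc[[i for i in table.counts.index if i.startswith("SF1_")]]
        assert sf1["condB"].mean() > 3 * sf1["condA"].mean()


class TestMutateCodons:
    def test_identity(self):
        assert mutate_codons("ATGAAA", 0, 0, seed=1) == "ATGAAA"

    def test_forced_synonymous_change(self):
        out = mutate_codons("TTT" * 10, 1, 0, seed=2)
        assert out.count("TTC") == 1 and out.count("TTT") == 9

    def test_infeasible_request(self):
        with pytest.raises(ValueError, match="infeasible"):
            mutate_codons("ATG", 1, 0, seed=1)  # ATG has no synonymous change

    def test_no_stops_introduced(self):
        out = mutate_codons("TGGCGATCA" * 10, 5, 5, seed=3)
        codons = [out[i : i + 3] for i in range(0, len(out), 3)]
        assert not set(codons) & {"TAA", "TAG", "TGA"}


class TestSampleHmmColumns:
    def test_shapes_and_determinism(self):
        params = HmmParams()
        c1, s1 = sample_hmm_columns(100, params, seed=4)
        c2, s2 = sample_hmm_columns(100, params, seed=4)
        assert c1 == c2 and np.array_equal(s1, s2)
        assert len(c1) == 100 and set(np.unique(s1)) <= {0, 1}

    def test_coverage_near_target(self):
        params = HmmParams(target_coverage=0.3)
        _, states = sample_hmm_columns(20_000, params, seed=5)
        assert abs(states.mean() - 0.3) < 0.05
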