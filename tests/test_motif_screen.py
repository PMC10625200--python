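"""Motif scanning, TSS context scoring, interval projection and promoter calls."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oopromscan.io_formats import GenomicSequence, MultipleAlignment
from oopromscan.motif_screen import (IUPAC, MotifModel, TssContextModel,
                                     call_promoters, project_ref_interval,
                                     reverse_complement, scan_motif,
                                     score_tss_context)

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AACN", "NGTT")])
    def test_examples(self, seq, expected):
        assert reverse_complement(GenomicSequence(id="x", residues=seq)).residues == expected

    @given(dna)
    @settings(max_examples=100, derandomize=True)
    def test_involution(self, seq):
        s = GenomicSequence(id="x", residues=seq)
        back = reverse_complement(reverse_complement(s))
        assert back.residues == s.residues and back.strand == s.strand

    def test_strand_flips(self):
        assert reverse_complement(GenomicSequence(id="x", residues="A")).strand == "-"


class TestScanMotif:
    def test_exact_hit(self):
        hits = scan_motif("GGTTCTTAAGG", MotifModel(max_mismatches=0))
        assert len(hits) == 1 and hits[0].start == 2 and hits[0].mismatches == 0

    def test_one_mismatch(self):
        hits = scan_motif("GGTTCTTATGG", MotifModel(max_mismatches=1))
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_iupac_w(self):
        model = MotifModel(consensus="TTCTWAA", max_mismatches=0)
        for seq in ("TTCTTAA", "TTCTAAA"):
            assert scan_motif(seq, model)[0].mismatches == 0

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            MotifModel(consensus="TTCZAA")

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(7, 60)))
            cons = "".join(rng.choice(list(IUPAC), size=rng.integers(3, 8)))
            mm_cap = int(rng.integers(0, 3))
            model = MotifModel(consensus=cons, max_mismatches=mm_cap)
            hits = scan_motif(seq, model)
            expected = []
            for i in range(len(seq) - len(cons) + 1):
                mm = sum(1 for b, c in zip(seq[i:], cons) if b not in IUPAC[c])
                if mm <= mm_cap:
                    expected.append((mm, i))
            assert [(h.mismatches, h.start) for h in hits] == sorted(expected)

    @given(dna, st.integers(min_value=0, max_value=3))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_mismatch_budget(self, seq, mm):
        if len(seq) < 7:
            seq = seq + "ACGTACG"
        lo = scan_motif(seq, MotifModel(max_mismatches=mm))
        hi = scan_motif(seq, MotifModel(max_mismatches=mm + 1))
        assert {(h.start) for h in lo} <= {(h.start) for h in hi}


class TestTssContext:
    def test_perfect_context(self):
        seq = "CTCTCTCTCT" + "GAGAGAGAGA"
        ct, ga, ok = score_tss_context(seq, 10, TssContextModel())
        assert (ct, ga, ok) == (1.0, 1.0, True)

    def test_all_g_upstream_fails(self):
        ct, ga, ok = score_tss_context("GGGGGGGGGG" + "GAGAGAGAGA", 10, TssContextModel())
        assert ct == 0.0 and not ok

    def test_partial_fraction(self):
        seq = "CTCTGGCTCT" + "GAGAGAGAGA"
        ct, _, ok = score_tss_context(seq, 10, TssContextModel(ct_min_fraction=0.8))
        assert ct == pytest.approx(0.8) and ok
        _, _, strict = score_tss_context(seq, 10, TssContextModel(ct_min_fraction=0.81))
        assert not strict

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            score_tss_context("ACGT", 9, TssContextModel())

    def test_edge_truncation(self):
        ct, ga, _ = score_tss_context("CTGA", 2, TssContextModel())
        assert ct == 1.0 and ga == 1.0


class TestProjection:
    def test_gap_skip(self):
        aln = MultipleAlignment({"ref": "A-CG", "sp": "ATCG"})
        proj = project_ref_interval(aln, "ref", 1, 3)
        assert proj["ref"].columns == (2, 4)
        assert proj["sp"].substring == "CG"

    def test_all_gap_projection(self):
        aln = MultipleAlignment({"ref": "ACGT", "sp": "A--T"})
        proj = project_ref_interval(aln, "ref", 1, 3)
        assert proj["sp"].gap_fraction == 1.0 and proj["sp"].substring == ""

    def test_full_interval_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            rows = {}
            for sp in ("a", "b", "c"):
                rows[sp] = "".join(rng.choice(list("ACGT-"), size=n))
            # ensure at least one residue per row
            rows = {sp: (r if set(r) != {"-"} else "A" + r[1:]) for sp, r in rows.items()}
            aln = MultipleAlignment(rows)
            ref_ungapped = aln.ungapped("a").residues
            proj = project_ref_interval(aln, "a", 0, len(ref_ungapped))
            assert proj["a"].substring == ref_ungapped

    def test_missing_ref_species(self):
        aln = MultipleAlignment({"a": "ACGT"})
        with pytest.raises(ValueError, match="absent"):
            project_ref_interval(aln, "zz", 0, 1)


def _signature_alignment():
    """Three species sharing the promoter block, one diverged, one deleted."""
    block = "TTCTTAA" + "CT" * 12 + "C" + "A" + "GAGAGAGAGA"
    flank5, flank3 = "GGCCGGCCGG", "CCGGCCGGCC"
    row = flank5 + block + flank3
    mutated = row.replace("TTCTTAA", "TTCTTAT", 1)  # 1 mismatch in the motif
    background = flank5 + "G" * len(block) + flank3
    deleted = flank5 + "-" * len(block) + flank3
    return MultipleAlignment({
        "mouse": row, "rat": row, "hamster": mutated,
        "vole": deleted, "squirrel": background,
    })


class TestCallPromoters:
    def test_statuses(self):
        aln = _signature_alignment()
        calls = {c.species: c for c in call_promoters(aln, "mouse", 10 + 32)}
        assert calls["mouse"].status == "present"
        assert calls["rat"].status == "present"
        assert calls["hamster"].status == "present"  # 1 mm <= default budget
        assert calls["vole"].status == "region_deleted"
        assert calls["squirrel"].status == "absent"
        assert calls["mouse"].tss_offset_observed == 32

    def test_partial_band_semantics(self):
        aln = _signature_alignment()
        strict = MotifModel(max_mismatches=0)
        calls = {c.species: c.status for c in
                 call_promoters(aln, "mouse", 42, motif=strict, partial_max=2)}
        assert calls["hamster"] == "partial"
        three_label = {c.species: c.status for c in
                       call_promoters(aln, "mouse", 42, motif=strict, partial_max=0)}
        assert three_label["hamster"] == "absent"

    def test_anchor_failure(self):
        aln = _signature_alignment()
        with pytest.raises(ValueError, match="anchor"):
            call_promoters(aln, "squirrel", 42)

    def test_context_failure_gives_partial(self):
        # motif present but TSS context ruined in one species
        block = "TTCTTAA" + "CT" * 12 + "C" + "A" + "GAGAGAGAGA"
        bad = "TTCTTAA" + "GG" * 12 + "G" + "A" + "GAGAGAGAGA"
        aln = MultipleAlignment({"ref": "GG" + block, "sp": "GG" + bad})
        calls = {c.species: c.status for c in call_promoters(aln, "ref", 2 + 32)}
        assert calls["ref"] == "present" and calls["sp"] == "partial"

    def test_generator_truth_recovery_zero_rate(self):
        from oopromscan.io_formats import parse_newick
        from oopromscan.synthetic_data import MotifPlantSpec, evolve_alignment
        tree = parse_newick("((m:1,r:1):1,(h:1,(x:1,y:1):1):1);")
        block = "TTCTTAA" + "CT" * 12 + "C" + "A" + "GAGAGAGAGA"
        ancestor = GenomicSequence(id="anc", residues="G" * 60 + "C" * 60)
        plant = MotifPlantSpec(clade_leaves={"m", "r"}, motif=block, offset_in_ancestor=10)
        aln, truth = evolve_alignment(tree, ancestor, 0.0, 0.0, plant, seed=3)
        ref_tss = truth["motif_start"]["m"] + 32
        calls = {c.species: c.status for c in call_promoters(aln, "m", ref_tss, partial_max=1)}
        assert calls == truth["status"]
        assert truth["motif_start"]["m"] == 10  # zero-rate: offset maps through

    def test_raising_ct_threshold_never_grows_pass_set(self):
        aln = _signature_alignment()
        lo = {c.species for c in call_promoters(
            aln, "mouse", 42, context=TssContextModel(ct_min_fraction=0.5))
            if c.status == "present"}
        hi = {c.species for c in call_promoters(
            aln, "mouse", 42, context=TssContextModel(ct_min_fraction=0.95))
            if c.status == "present"}
        assert hi <= lo
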