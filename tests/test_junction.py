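"""Junction mapping, repair classification, validation, donors, filler origin."""

import numpy as np
import pytest

from breakscan import (
    Genome,
    apply_allele,
    classify_repair,
    design_validation_primers,
    extract_donors,
    locate_filler_origin,
    map_junction,
    validate_junction,
)
from breakscan.errors import (
    BreakscanError,
    DataError,
    NoJunctionError,
    RepetitiveFlankError,
    RepetitiveJunctionError,
)
from breakscan.genome import AlleleModel
from breakscan.junction import JunctionCall
from breakscan._seq import revcomp
from breakscan.simulate import random_allele_genome

TOY_REF = Genome("toy", "A" * 10 + "C" * 10 + "G" * 10 + "T" * 10)


class TestMapJunction:
    def test_blunt_junction_on_homopolymer_blocks(self):
        call = map_junction("A" * 10 + "T" * 10, TOY_REF, min_anchor=10)
        assert (call.north_bp, call.south_bp) == (10, 31)
        assert call.deletion_size == 20
        assert call.filler == "" and call.microhomology == ""

    def test_microhomology_left_aligned(self):
        ref = Genome("r", "GGGGACTTTTTTTTACAAAA")
        call = map_junction("GGGGACAAAA", ref, min_anchor=4)
        assert call.microhomology == "AC"
        assert (call.north_bp, call.south_bp) == (4, 15)
        assert call.deletion_size == 10

    def test_filler_recovered(self):
        # filler chosen so it cannot blend into either flank ('G' would
        # extend the suffix anchor, 'C' the prefix anchor)
        read = "A" * 10 + "GAGAT" + "T" * 10
        call = map_junction(read, TOY_REF, min_anchor=10)
        assert call.filler == "GAGAT"
        assert (call.north_bp, call.south_bp) == (10, 31)

    def test_contiguous_read_raises_no_junction(self):
        with pytest.raises(NoJunctionError):
            map_junction(TOY_REF.sub(5, 30), TOY_REF, min_anchor=10)

    def test_both_sides_repetitive_raises(self):
        ref = Genome("r", "ACGT" * 50)
        with pytest.raises(RepetitiveJunctionError):
            map_junction("ACGT" * 5 + "GTAC" * 5, ref, min_anchor=8)

    def test_repetitive_north_flank_reports_unmappable(self, scaled_fixture):
        fx = scaled_fixture
        allele = fx.allele("bp-2")
        mutant = fx.mutants["bp-2"]
        j = allele.north_bp  # junction position in mutant coords (no filler)
        read = mutant.sub(j - 300, j + 300)
        call = map_junction(read, fx.reference, min_anchor=20)
        assert not call.north_mappable
        assert call.south_mappable
        assert call.south_bp == allele.south_bp

    def test_symmetry_under_reverse_complement(self, rng):
        for _ in range(20):
            ref, allele, mutant = random_allele_genome(rng, genome_len=6_000)
            j = allele.north_bp + len(allele.filler)
            read = mutant.sub(j - 120, j + 120)
            call = map_junction(read, ref, min_anchor=20)
            flipped = map_junction(
                revcomp(read), Genome("rc", revcomp(ref.sequence)), min_anchor=20
            )
            L = len(ref)
            assert flipped.deletion_size == call.deletion_size
            assert flipped.filler == revcomp(call.filler)
            # mirrored coordinates; a blunt ambiguous junction left-aligns on
            # the flipped genome too, i.e. right-aligns in original frame
            m = 0 if call.filler else len(call.microhomology)
            assert L - flipped.south_bp + 1 == call.north_bp + m
            assert L - flipped.north_bp + 1 == call.south_bp + m


from oracles import leftmost_blunt_placement as oracle_leftmost_placement


class TestRecoveryProperty:
    def test_100_random_alleles_recovered_exactly(self, rng):
        for _ in range(100):
            ref, allele, mutant = random_allele_genome(rng, genome_len=20_000)
            j = allele.north_bp + len(allele.filler)
            read = mutant.sub(j - 200, j + 200)
            call = map_junction(read, ref, min_anchor=20, allele=allele.name)
            assert call.north_mappable and call.south_mappable
            assert (call.north_bp, call.south_bp) == (allele.north_bp, allele.south_bp)
            assert call.filler == allele.filler
            assert len(call.microhomology) == allele.microhomology_len
            assert call.deletion_size == allele.south_bp - allele.north_bp - 1

    def test_left_alignment_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            ref, allele, mutant = random_allele_genome(
                rng, genome_len=6_000, max_filler=0, max_microhomology=4
            )
            j = allele.north_bp
            read = mutant.sub(j - 40, j + 40)
            call = map_junction(read, ref, min_anchor=15)
            oracle = oracle_leftmost_placement(read, ref.sequence)
            assert oracle is not None
            assert (call.north_bp, call.south_bp, call.filler) == oracle


class TestClassifyRepair:
    def test_fixture_signatures(self, scaled_result):
        calls = scaled_result.calls
        assert calls["bp-3"].repair_flags == {"filler_insertion"}
        assert calls["bp-11"].repair_flags == {"blunt_nhej"}
        assert calls["bp-5"].repair_flags == {"filler_insertion", "microhomology"}

    def test_single_base_homology_not_flagged(self):
        call = JunctionCall("x", 100, 201, "", "A", True, True)
        assert classify_repair(call) == {"blunt_nhej"}

    def test_unmappable_side_cannot_be_classified(self):
        call = JunctionCall("x", None, 201, "", "", False, True)
        with pytest.raises(BreakscanError):
            classify_repair(call)


class TestValidationPrimers:
    def test_designed_pair_amplifies_mutant_not_reference(self, scaled_fixture, scaled_result):
        from breakscan import amplify

        fx = scaled_fixture
        call = scaled_result.calls["bp-3"]
        pair = design_validation_primers(
            call, fx.reference, fx.mutants["bp-3"], target_size=500
        )
        assert amplify(fx.mutants["bp-3"], pair).status == "present"
        # on the reference the same pair must span the whole deletion, so it
        # fails under any ceiling below deletion + target size
        assert amplify(fx.reference, pair, max_product=2_000).status == "absent"
        ref_call = amplify(fx.reference, pair, max_product=10_000)
        truth = fx.allele("bp-3")
        assert ref_call.size == amplify(fx.mutants["bp-3"], pair).size + truth.deletion_size - len(truth.filler)

    def test_repetitive_flank_raises(self, scaled_fixture):
        fx = scaled_fixture
        allele = fx.allele("bp-2")
        forced = JunctionCall(
            "bp-2", allele.north_bp, allele.south_bp, "", "", True, True
        )
        with pytest.raises(RepetitiveFlankError):
            design_validation_primers(
                forced, fx.reference, fx.mutants["bp-2"], target_size=500
            )

    def test_degenerate_target_size_rejected(self, scaled_fixture, scaled_result):
        fx = scaled_fixture
        with pytest.raises(DataError):
            design_validation_primers(
                scaled_result.calls["bp-3"], fx.reference, fx.mutants["bp-3"],
                target_size=30,
            )


class TestValidateJunction:
    def test_fixture_pass_contains_filler(self, scaled_fixture, scaled_result):
        fx = scaled_fixture
        call = scaled_result.calls["bp-5"]
        pair = design_validation_primers(
            call, fx.reference, fx.mutants["bp-5"], target_size=500
        )
        result = validate_junction(fx.mutants["bp-5"], pair, call, fx.reference)
        assert result.passed
        assert fx.allele("bp-5").filler in result.product

    def test_wrong_template_fails(self, scaled_fixture, scaled_result):
        fx = scaled_fixture
        call = scaled_result.calls["bp-5"]
        pair = design_validation_primers(
            call, fx.reference, fx.mutants["bp-5"], target_size=500
        )
        result = validate_junction(fx.mutants["bp-11"], pair, call, fx.reference)
        assert not result.passed

    def test_corrupted_template_fails_sequence_check(self, scaled_fixture, scaled_result):
        fx = scaled_fixture
        call = scaled_result.calls["bp-3"]
        mutant = fx.mutants["bp-3"]
        pair = design_validation_primers(call, fx.reference, mutant, target_size=500)
        j = call.north_bp + len(call.filler)
        seq = list(mutant.sequence)
        seq[j - 5] = "A" if seq[j - 5] != "A" else "C"  # 1-nt corruption in product
        corrupted = Genome("bp-3x", "".join(seq))
        result = validate_junction(corrupted, pair, call, fx.reference)
        assert not result.passed
        assert result.reason == "sequence mismatch"


class TestDonors:
    def test_index_arithmetic_on_toy_reference(self):
        call = JunctionCall("t", 10, 31, "", "", True, True)
        pair = extract_donors(TOY_REF, call, flank=5)
        assert pair.north_donor == "AAAAACCCCC"
        assert pair.south_donor == "GGGGGTTTTT"
        assert not pair.notes

    def test_truncation_noted_at_chromosome_end(self):
        call = JunctionCall("t", 3, 31, "", "", True, True)
        pair = extract_donors(TOY_REF, call, flank=5)
        assert any("north donor truncated" in n for n in pair.notes)

    def test_interior_donors_have_full_width(self, scaled_fixture, scaled_result):
        fx = scaled_fixture
        call = scaled_result.calls["bp-11"]
        pair = extract_donors(fx.reference, call, flank=250)
        assert len(pair.north_donor) == 500 == len(pair.south_donor)


class TestFillerOrigin:
    def test_exact_copy_reported_with_identity_one(self):
        filler = "TCCATGTAGTAAGGTAATT"
        decoy = Genome("d", "G" * 50 + filler + "G" * 50)
        hits = locate_filler_origin(filler, [decoy])
        assert hits[0].identity == 1.0 and hits[0].start == 51

    def test_one_mismatch_in_19mer_reported(self):
        filler = "TCCATGTAGTAAGGTAATT"
        near = filler[:9] + "C" + filler[10:]
        assert near != filler
        decoy = Genome("d", "G" * 30 + near + "G" * 30)
        hits = locate_filler_origin(filler, [decoy], min_identity=0.90)
        assert hits and abs(hits[0].identity - 18 / 19) < 1e-12

    def test_two_mismatches_fall_below_threshold(self):
        filler = "TCCATGTAGTAAGGTAATT"
        near = "AG" + filler[2:]
        decoy = Genome("d", "G" * 30 + near + "G" * 30)
        assert locate_filler_origin(filler, [decoy], min_identity=0.90) == []

    def test_minus_strand_hit_coordinates(self):
        filler = "TCCATGTAGTAAGGTAATT"
        decoy = Genome("d", "G" * 40 + revcomp(filler) + "G" * 41)
        hits = locate_filler_origin(filler, [decoy])
        assert hits[0].strand == "-" and hits[0].start == 41

    def test_fixture_decoy_contains_near_identical_filler(self, scaled_fixture):
        fx = scaled_fixture
        hits = locate_filler_origin(fx.allele("bp-5").filler, [fx.decoy])
        assert hits and hits[0].identity >= 0.90
        assert hits[0].genome == "chr3-like"
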