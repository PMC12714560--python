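"""Microhomology scanner vs brute force, classification, logos, repeat checks."""

import math
import random

import numpy as np
import pytest

from deletion_scope.model import ISElement, JunctionCall, revcomp
from deletion_scope.signatures import (
    classify_junction,
    flank_matrix,
    microhomology,
    verify_inverted_repeats,
)
from tests.test_synthetic import brute_force_mh


def make_call(lb, rb):
    return JunctionCall("chr", lb, rb, 1, [(lb, rb, 1)])


class TestMicrohomology:
    def test_left_extension_example(self):
        ref = "GGGGACGTTTTTTTTTACGTCCCC"
        mh = microhomology(ref, 8, 20)
        assert (mh.left_ext, mh.right_ext, mh.total) == (4, 0, 4)
        assert mh.mh_sequence == "ACGT"

    def test_boundary_capping(self):
        mh = microhomology("AAAAAAAAAA", 2, 6)
        assert (mh.left_ext, mh.right_ext, mh.total) == (2, 4, 6)

    def test_zero_when_flanks_differ(self):
        ref = "ACGTACGTAC"
        # a=4: ref[3]=T vs ref[7]=T ... construct explicit mismatch
        ref = "AAACTTTTGG"
        mh = microhomology(ref, 4, 8)
        assert ref[3] != ref[7] and ref[4] != ref[8]
        assert mh.total == 0

    def test_invalid_coordinates_error(self):
        with pytest.raises(ValueError):
            microhomology("ACGT", 2, 2)
        with pytest.raises(ValueError):
            microhomology("ACGT", 1, 9)

    def test_matches_brute_force_on_random_triples(self):
        rng = random.Random(42)
        for _ in range(1000):
            n = rng.randint(10, 80)
            ref = "".join(rng.choice("ACGT") for _ in range(n))
            a = rng.randint(0, n - 2)
            b = rng.randint(a + 1, n)
            mh = microhomology(ref, a, b)
            assert (mh.left_ext, mh.right_ext) == brute_force_mh(ref, a, b)

    def test_ambiguity_interval_placements_equivalent(self):
        rng = random.Random(7)
        for _ in range(200):
            n = rng.randint(20, 100)
            ref = "".join(rng.choice("AC") for _ in range(n))  # binary -> frequent MH
            a = rng.randint(2, n - 5)
            b = rng.randint(a + 1, n - 1)
            mh = microhomology(ref, a, b)
            size = b - a
            alleles = {
                ref[:x] + ref[x + size :]
                for x in range(mh.ambiguity_interval[0], mh.ambiguity_interval[1] + 1)
            }
            assert len(alleles) == 1


IS = ISElement("IS1_1", 10_000, 10_768, irl=(10_000, 10_030), irr=(10_738, 10_768))


class TestClassifyJunction:
    def test_breakpoint_at_irr_end_is_associated(self):
        call = make_call(2_000, 10_768)
        mh = microhomology("A" * 20_000, 2_000, 10_768)
        cls = classify_junction(call, mh, [IS])
        assert cls.label == "IS_ASSOCIATED"
        assert (cls.element_id, cls.end, cls.distance) == ("IS1_1", "IRR", 0)

    def test_microhomology_when_no_is_nearby(self):
        ref = "GGGG" + "ACGTACGTACG" + "TTTTTTTTT" + "ACGTACGTACG" + "CCCC"
        a, b = 15, 35
        mh = microhomology(ref, a, b)
        assert mh.total >= 2
        cls = classify_junction(make_call(a, b), mh, [IS], min_mh=2)
        assert cls.label == "MICROHOMOLOGY"

    def test_other_fallthrough(self):
        ref = "AAACTTTTGG"
        mh = microhomology(ref, 4, 8)
        cls = classify_junction(make_call(4, 8), mh, [IS])
        assert cls.label == "OTHER"

    def test_is_precedence_over_microhomology(self):
        call = make_call(2_000, 10_766)  # 2 bp from IRR end, within is_dist=3
        mh = microhomology("A" * 20_000, 2_000, 10_766)  # homopolymer: huge MH
        cls = classify_junction(call, mh, [IS])
        assert cls.label == "IS_ASSOCIATED" and cls.distance == 2

    def test_planted_mechanisms_recovered(self, scenario):
        """Classification recovers every planted mechanism at defaults."""
        for key, ev in scenario.events.items():
            mh = microhomology(scenario.genome.sequence, ev.left_break, ev.right_break)
            cls = classify_junction(
                make_call(ev.left_break, ev.right_break),
                mh,
                scenario.genome.is_elements,
            )
            if ev.mechanism == "IS_BOUNDED":
                assert cls.label == "IS_ASSOCIATED"
                assert cls.element_id == ev.bounded_element_id
                assert cls.end == ev.bounded_end
            else:
                assert cls.label == "MICROHOMOLOGY"
                assert cls.mh_total >= ev.planted_mh_len


class TestFlankMatrix:
    def test_identical_flanks_give_two_bits_everywhere(self):
        ref = "T" * 100 + "ACGTACGTAC" * 3 + "G" * 100
        calls = [make_call(10, 100) for _ in range(5)]
        pfm = flank_matrix(calls, ref, side="RIGHT", window=20, orientation="DOWNSTREAM")
        assert pfm.n_sequences == 5
        assert np.allclose(pfm.information_content, 2.0)
        assert (pfm.counts.sum(axis=0) == 5).all()

    def test_half_half_column_is_one_bit(self):
        ref_a = "A" * 40
        ref_c = "C" * 40
        # two calls on A-flank, two on C-flank positions
        ref = ref_a + ref_c
        calls = [make_call(1, 10), make_call(1, 10), make_call(1, 50), make_call(1, 50)]
        pfm = flank_matrix(calls, ref, side="RIGHT", window=5, orientation="DOWNSTREAM")
        assert np.allclose(pfm.information_content, 1.0)

    def test_random_flanks_low_information(self):
        rng = random.Random(3)
        ref = "".join(rng.choice("ACGT") for _ in range(20_000))
        calls = [make_call(1, rng.randint(100, 19_000)) for _ in range(50)]
        pfm = flank_matrix(calls, ref, side="RIGHT", window=30)
        assert pfm.information_content.mean() < 0.15

    def test_upstream_left_extracts_retained_flank(self):
        ref = "AACCGGTTAACCGGTT"
        calls = [make_call(8, 12)]
        pfm = flank_matrix(calls, ref, side="LEFT", window=4, orientation="UPSTREAM")
        # ref[4:8] == "GGTT"
        counts = {base: pfm.counts[i].tolist() for i, base in enumerate("ACGT")}
        assert counts["G"] == [1, 1, 0, 0]
        assert counts["T"] == [0, 0, 1, 1]

    def test_out_of_bounds_calls_skipped_and_empty_errors(self):
        ref = "ACGT" * 10
        with pytest.raises(ValueError):
            flank_matrix([make_call(1, 39)], ref, side="RIGHT", window=10)
        with pytest.raises(ValueError):
            flank_matrix([make_call(1, 5)], ref, window=0)


class TestInvertedRepeats:
    def test_exact_repeats_zero_mismatches(self):
        core = "ACGTTGCACGGTATCCGTAGGCTAACGTGA"
        elem = core + "N" * 0 + "T" * 708 + revcomp(core)
        irl, irr, mism = verify_inverted_repeats(elem, 30)
        assert mism == 0 and irl == core

    def test_single_substitution_detected(self):
        core = "ACGTTGCACGGTATCCGTAGGCTAACGTGA"
        tail = list(revcomp(core))
        tail[5] = "A" if tail[5] != "A" else "C"
        elem = core + "T" * 708 + "".join(tail)
        assert verify_inverted_repeats(elem, 30)[2] == 1

    def test_random_element_mismatch_rate(self):
        rng = random.Random(11)
        rates = []
        for _ in range(200):
            elem = "".join(rng.choice("ACGT") for _ in range(768))
            rates.append(verify_inverted_repeats(elem, 30)[2] / 30)
        assert math.isclose(sum(rates) / len(rates), 0.75, abs_tol=0.03)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            verify_inverted_repeats("ACGT", 3)
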