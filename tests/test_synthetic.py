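"""Generator invariants: IS architecture, planted signatures, read bookkeeping."""

import math

import numpy as np
import pytest

from deletion_scope.model import GenomeModel, Lineage, SimulationParams, revcomp
from deletion_scope.signatures import microhomology, verify_inverted_repeats
from deletion_scope.synthetic import build_genome, plant_deletion, simulate_pool


def brute_force_mh(ref: str, a: int, b: int, max_m: int = 50):
    """Independent character-scan oracle for breakpoint microhomology."""
    left = 0
    for i in range(max_m):
        if a - 1 - i < 0 or ref[a - 1 - i] != ref[b - 1 - i]:
            break
        left += 1
    right = 0
    for i in range(max_m):
        if b + i >= len(ref) or ref[a + i] != ref[b + i]:
            break
        right += 1
    return left, right


class TestBuildGenome:
    def test_is_elements_have_exact_inverted_repeats(self):
        g = build_genome(length=200_000, n_is=4, is_length=768, ir_length=30, seed=1)
        assert len(g.is_elements) == 4
        for e in g.is_elements:
            assert e.end - e.start == 768
            seq = g.slice(e.start, e.end)
            irl, irr, mism = verify_inverted_repeats(seq, 30)
            assert mism == 0
            assert irl == revcomp(irr)

    def test_all_is_copies_identical(self):
        g = build_genome(length=100_000, n_is=3, seed=3)
        seqs = {g.slice(e.start, e.end) for e in g.is_elements}
        assert len(seqs) == 1

    def test_degenerate_no_features(self):
        g = build_genome(length=5_000, n_is=0, gene_spec=[], seed=0)
        assert g.features == [] and g.is_elements == []
        assert set(g.sequence) <= set("ACGT")

    def test_deterministic_for_fixed_seed(self):
        g1 = build_genome(length=20_000, n_is=2, seed=7)
        g2 = build_genome(length=20_000, n_is=2, seed=7)
        assert g1.sequence == g2.sequence
        assert g1.is_elements == g2.is_elements

    def test_features_do_not_overlap(self):
        g = build_genome(
            length=50_000, n_is=3, gene_spec=[("a", 2000), ("b", 1500)], seed=5
        )
        ivs = sorted(g.all_feature_intervals())
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            build_genome(length=1_000, n_is=4, is_length=768, seed=0)


class TestPlantDeletion:
    def test_aej_microhomology_verifiable_by_oracle(self):
        g = build_genome(length=30_000, n_is=0, seed=2)
        _, ev = plant_deletion(g, "AEJ", size=150, mh_len=4, seed=9)
        left, right = brute_force_mh(g.sequence, ev.left_break, ev.right_break)
        assert left >= 4

    def test_is_bounded_right_break_at_irr_end(self):
        g = build_genome(length=100_000, n_is=2, seed=4)
        elem = g.is_elements[-1]
        _, ev = plant_deletion(g, "IS_BOUNDED", size=5_000, anchor=(elem.id, "IRR"))
        assert ev.right_break == elem.irr[1]
        assert ev.left_break == elem.irr[1] - 5_000
        assert ev.bounded_element_id == elem.id and ev.bounded_end == "IRR"

    def test_blunt_has_zero_microhomology(self):
        g = build_genome(length=30_000, n_is=0, seed=6)
        _, ev = plant_deletion(g, "BLUNT", size=200, seed=11)
        assert microhomology(g.sequence, ev.left_break, ev.right_break).total == 0

    def test_derived_allele_is_sequence_minus_deletion(self):
        g = build_genome(length=10_000, n_is=0, seed=8)
        allele, ev = plant_deletion(g, "AEJ", size=100, mh_len=3, seed=1)
        assert allele == g.sequence[: ev.left_break] + g.sequence[ev.right_break :]
        assert len(allele) == len(g.sequence) - 100

    def test_mh_range_enforcement(self):
        g = build_genome(length=10_000, n_is=0, seed=8)
        with pytest.raises(ValueError):
            plant_deletion(g, "AEJ", size=100, mh_len=20, mh_range=(2, 11), seed=1)


@pytest.fixture(scope="module")
def single_pool():
    g = build_genome(length=40_000, n_is=1, seed=13)
    _, ev = plant_deletion(g, "IS_BOUNDED", size=5_000, anchor="auto")
    lin = Lineage(id="only", deletions=(ev,), pool_fraction=1.0)
    params = SimulationParams(depth=30, read_length=100, seed=21)
    return g, ev, simulate_pool(g, [lin], params)


class TestSimulatePool:
    def test_no_read_starts_inside_deleted_interval(self, single_pool):
        _, ev, pool = single_pool
        assert all(
            not (ev.left_break <= r.pos0 < ev.right_break) for r in pool.reads
        )

    def test_junction_reads_carry_exact_n_gap(self, single_pool):
        _, ev, pool = single_pool
        n_reads = [r for r in pool.reads if any(op == "N" for op, _ in r.cigar)]
        assert n_reads, "expected junction-spanning reads"
        for r in n_reads:
            gaps = [l for op, l in r.cigar if op == "N"]
            assert gaps == [ev.size]

    def test_read_count_conservation(self, single_pool):
        g, ev, pool = single_pool
        retained = len(g) - ev.size
        expected = math.ceil(30 * retained / 100)
        assert pool.n_drawn == expected
        assert len(pool.reads) == pool.n_drawn - pool.n_anchor_dropped

    def test_cigar_reference_span_consistency(self, single_pool):
        _, ev, pool = single_pool
        for r in pool.reads:
            span = r.reference_span()
            n_gap = sum(l for op, l in r.cigar if op == "N")
            assert span == 100 + n_gap

    def test_min_anchor_segments(self, single_pool):
        _, _, pool = single_pool
        for r in pool.reads:
            if len(r.cigar) > 1:
                assert all(l >= 10 for op, l in r.cigar if op == "M")

    def test_deterministic_sam_bytes(self):
        g = build_genome(length=20_000, n_is=0, seed=3)
        _, ev = plant_deletion(g, "AEJ", size=120, mh_len=3, seed=5)
        lin = Lineage(id="l", deletions=(ev,), pool_fraction=1.0)
        params = SimulationParams(depth=10, read_length=100, seed=17)
        sam1 = simulate_pool(g, [lin], params).sam_text
        sam2 = simulate_pool(g, [lin], params).sam_text
        assert sam1 == sam2

    def test_half_pool_halves_depth_in_deletion(self):
        g = build_genome(length=30_000, n_is=0, seed=31)
        _, ev = plant_deletion(g, "AEJ", size=2_000, mh_len=3, seed=7)
        carrier = Lineage(id="del", deletions=(ev,), pool_fraction=0.5)
        wt = Lineage(id="wt", deletions=(), pool_fraction=0.5)
        params = SimulationParams(depth=40, read_length=100, seed=23)
        pool = simulate_pool(g, [carrier, wt], params)
        depth = np.zeros(len(g))
        for r in pool.reads:
            cur = r.pos0
            for op, l in r.cigar:
                if op == "M":
                    depth[cur : cur + l] += 1
                if op in "MN":
                    cur += l
        inside = depth[ev.left_break + 200 : ev.right_break - 200].mean()
        outside = depth[1_000 : ev.left_break - 200].mean()
        assert inside / outside == pytest.approx(0.5, abs=0.1)

    def test_fraction_sum_validated(self):
        g = build_genome(length=20_000, n_is=0, seed=3)
        lin = Lineage(id="l", deletions=(), pool_fraction=0.5)
        with pytest.raises(ValueError, match="fractions"):
            simulate_pool(g, [lin], SimulationParams(seed=1))

    def test_mapq_low_fraction_emitted(self):
        g = build_genome(length=20_000, n_is=0, seed=3)
        lin = Lineage(id="l", deletions=(), pool_fraction=1.0)
        params = SimulationParams(depth=10, seed=19, mapq_low_fraction=0.2)
        pool = simulate_pool(g, [lin], params)
        mapqs = {r.mapq for r in pool.reads}
        assert mapqs == {1, 60}
        frac_low = sum(r.mapq == 1 for r in pool.reads) / len(pool.reads)
        assert frac_low == pytest.approx(0.2, abs=0.05)


def test_sam_parses_with_pysam(scenario_sam):
    import pysam

    with pysam.AlignmentFile(str(scenario_sam)) as af:
        n = sum(1 for _ in af)
    assert n > 10_000


def test_truth_table_support_matches_emitted_junction_reads(scenario):
    counted = {}
    for r in scenario.pool.reads:
        cur = r.pos0
        for op, l in r.cigar:
            if op == "N" and r.mapq >= 60:
                counted[(cur, cur + l)] = counted.get((cur, cur + l), 0) + 1
            if op in "MN":
                cur += l
    for row in scenario.truth.itertuples():
        assert counted.get((row.left_break, row.right_break), 0) == row.expected_support
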