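import numpy as np
import pytest

from olcasm._align import edit_identity, overlap_align
from olcasm.consensus import (
    Contig,
    build_path_consensus,
    circularize,
    detect_active_regions,
    polish,
    realign,
)
from olcasm.overlap_graph import Edge
from olcasm.read_simulator import simulate_genome
from olcasm.seqio import Read, reverse_complement


def edge(a, b, overlap):
    return Edge((a, "e"), (b, "s"), overlap, int(overlap * 0.8), 0.9, 30)


class TestOverlapAlign:
    def test_exact_overlap_found(self):
        genome = simulate_genome(4_000, 0.5, seed=81).sequence
        tail, prefix = genome[:2_500], genome[1_500:3_500]
        identity, ov = overlap_align(tail[-1_500:], prefix[:1_500])
        assert ov == 1_000
        assert identity == 1.0

    def test_noisy_overlap_found_approximately(self):
        rng = np.random.default_rng(82)
        genome = simulate_genome(4_000, 0.5, seed=83).sequence
        prefix = list(genome[1_500:3_500])
        for i in rng.choice(len(prefix), 20, replace=False):
            prefix[i] = "ACGT"[(("ACGT".index(prefix[i])) + 1) % 4]
        identity, ov = overlap_align(genome[1_000:2_500], "".join(prefix[:1_500]))
        assert abs(ov - 1_000) <= 5
        assert identity > 0.95


class TestBuildPathConsensus:
    def test_exact_two_read_overlap_reproduces_template(self):
        genome = simulate_genome(5_000, 0.5, seed=84).sequence
        a, b = Read("A", genome[:3_000]), Read("B", genome[2_000:5_000])
        pieces = build_path_consensus(
            [("A", False), ("B", False)], [edge("A", "B", 1_000)], {"A": a, "B": b}
        )
        assert len(pieces) == 1
        assert pieces[0][0] == genome

    def test_indel_noisy_second_read_close_length(self):
        rng = np.random.default_rng(85)
        genome = simulate_genome(5_000, 0.5, seed=86).sequence
        b_seq = list(genome[2_000:5_000])
        for i in sorted(rng.choice(len(b_seq), 30, replace=False), reverse=True):
            if rng.random() < 0.5:
                del b_seq[i]
            else:
                b_seq.insert(i, "ACGT"[rng.integers(4)])
        pieces = build_path_consensus(
            [("A", False), ("B", False)],
            [edge("A", "B", 1_000)],
            {"A": Read("A", genome[:3_000]), "B": Read("B", "".join(b_seq))},
        )
        assert len(pieces) == 1
        assert abs(len(pieces[0][0]) - 5_000) / 5_000 < 0.01

    def test_singleton_path_is_the_read(self):
        r = Read("solo", "ACGT" * 100)
        pieces = build_path_consensus([("solo", False)], [], {"solo": r})
        assert pieces == [(r.sequence, pieces[0][1])]

    def test_reverse_oriented_first_read(self):
        genome = simulate_genome(5_000, 0.5, seed=87).sequence
        a = Read("A", reverse_complement(genome[:3_000]))
        b = Read("B", genome[2_000:5_000])
        pieces = build_path_consensus(
            [("A", True), ("B", False)], [edge("A", "B", 1_000)], {"A": a, "B": b}
        )
        assert pieces[0][0] == genome

    def test_bad_junction_splits_contig(self):
        a = Read("A", simulate_genome(3_000, 0.5, seed=88).sequence)
        b = Read("B", simulate_genome(3_000, 0.5, seed=89).sequence)  # unrelated
        pieces = build_path_consensus(
            [("A", False), ("B", False)], [edge("A", "B", 1_000)], {"A": a, "B": b}
        )
        assert len(pieces) == 2


class TestActiveRegions:
    def test_single_call_dilated(self):
        assert detect_active_regions(np.array([100]), 10_000) == [(95, 106)]

    def test_nearby_calls_merge(self):
        assert detect_active_regions(np.array([100, 108]), 10_000) == [(95, 114)]

    def test_no_calls(self):
        assert detect_active_regions(np.array([]), 10_000) == []

    def test_clamped_at_contig_bounds(self):
        assert detect_active_regions(np.array([2]), 10) == [(0, 8)]


def tiling_alignments(contig_len, read_len, step, genome):
    """Error-free reads tiling a contig, with their true placements."""
    from olcasm.consensus import Placement

    reads = {}
    placements = []
    for i, start in enumerate(range(0, contig_len - read_len + 1, step)):
        name = f"t{i}"
        reads[name] = Read(name, genome[start : start + read_len])
        placements.append(Placement(name, 0, start, False))
    return reads, placements


class TestPolish:
    def setup_case(self, seed=90):
        genome = simulate_genome(3_000, 0.5, seed=seed).sequence
        reads, placements = tiling_alignments(3_000, 600, 30, genome)
        return genome, reads, placements

    def test_planted_substitution_fixed_by_majority(self):
        genome, reads, placements = self.setup_case()
        broken = list(genome)
        broken[1_500] = "ACGT"[("ACGT".index(broken[1_500]) + 1) % 4]
        contigs = [Contig("c", "".join(broken))]
        alns = realign(contigs, placements, reads)
        polished = polish(contigs, alns, reads)
        assert polished[0].sequence == genome

    def test_planted_deletion_fixed_by_active_region(self):
        genome, reads, placements = self.setup_case(seed=91)
        broken = genome[:1_500] + genome[1_502:]  # 2-bp deletion
        contigs = [Contig("c", broken)]
        alns = realign(contigs, placements, reads)
        polished = polish(contigs, alns, reads)
        assert polished[0].sequence == genome

    def test_idempotent_on_perfect_consensus(self):
        genome, reads, placements = self.setup_case(seed=92)
        contigs = [Contig("c", genome)]
        alns = realign(contigs, placements, reads)
        polished = polish(contigs, alns, reads)
        assert polished[0].sequence == genome

    def test_coverage_one_region_unchanged(self):
        from olcasm.consensus import Placement

        genome = simulate_genome(1_000, 0.5, seed=93).sequence
        reads = {"only": Read("only", genome[200:400])}
        contigs = [Contig("c", genome)]
        alns = realign(contigs, [Placement("only", 0, 200, False)], reads)
        polished = polish(contigs, alns, reads)
        assert polished[0].sequence == genome


class TestContigRepair:
    def test_contained_contig_absorbed(self):
        from olcasm.consensus import Placement, rescue_unplaced

        genome = simulate_genome(20_000, 0.5, seed=98).sequence
        host = Contig("c1", genome)
        inner = Contig("c2", genome[6_000:8_500])
        reads = {
            "h": Read("h", genome[:2_000]),
            "i": Read("i", genome[6_000:8_000]),
        }
        placements = [Placement("h", 0, 0, False), Placement("i", 1, 0, False)]
        contigs, new_p = rescue_unplaced([host, inner], placements, reads)
        assert len(contigs) == 1
        moved = next(p for p in new_p if p.read_name == "i")
        assert abs(moved.start - 6_000) <= 100

    def test_dovetailing_contigs_merged(self):
        from olcasm.consensus import Placement, merge_overlapping_contigs

        genome = simulate_genome(16_000, 0.5, seed=99).sequence
        a = Contig("c1", genome[:9_000])
        b = Contig("c2", genome[6_000:16_000])
        reads = {
            "ra": Read("ra", genome[:2_000]),
            "rb": Read("rb", genome[14_000:16_000]),
        }
        placements = [Placement("ra", 0, 0, False), Placement("rb", 1, 8_000, False)]
        contigs, new_p = merge_overlapping_contigs([a, b], placements, reads)
        assert len(contigs) == 1
        assert contigs[0].sequence == genome
        rb = next(p for p in new_p if p.read_name == "rb")
        assert abs(rb.start - 14_000) <= 100

    def test_unrelated_contigs_untouched(self):
        from olcasm.consensus import Placement, merge_overlapping_contigs, rescue_unplaced

        a = Contig("c1", simulate_genome(8_000, 0.5, seed=100).sequence)
        b = Contig("c2", simulate_genome(6_000, 0.5, seed=101).sequence)
        reads = {"ra": Read("ra", a.sequence[:1_000]), "rb": Read("rb", b.sequence[:1_000])}
        placements = [Placement("ra", 0, 0, False), Placement("rb", 1, 0, False)]
        c1, _ = rescue_unplaced([a, b], placements, reads)
        c2, _ = merge_overlapping_contigs([a, b], placements, reads)
        assert len(c1) == 2 and len(c2) == 2


class TestCircularize:
    def test_rotation_to_origin(self):
        genome = simulate_genome(8_000, 0.5, seed=94).sequence
        cut = genome[3_000:] + genome[:3_000]
        origin = Read("ori", genome[:1_500])
        out = circularize([Contig("c1", cut)], [origin])
        assert out[0].sequence.startswith(genome[:1_000])

    def test_absent_origin_no_change(self):
        genome = simulate_genome(8_000, 0.5, seed=95).sequence
        other = simulate_genome(2_000, 0.5, seed=96).sequence
        out = circularize([Contig("c1", genome)], [Read("ori", other)])
        assert out[0].sequence == genome

    def test_reverse_strand_origin(self):
        genome = simulate_genome(8_000, 0.5, seed=97).sequence
        cut = reverse_complement(genome[3_000:] + genome[:3_000])
        origin = Read("ori", genome[:1_500])
        out = circularize([Contig("c1", cut)], [origin])
        assert edit_identity(out[0].sequence[:1_500], genome[:1_500]) > 0.95
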