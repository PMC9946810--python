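import itertools

import numpy as np
import pytest

from olcasm.consensus import AlignmentRecord, Contig
from olcasm.diploid_phasing import (
    FragmentMatrix,
    HetSite,
    build_fragment_matrix,
    call_het_sites,
    classify_blocks,
    mec_score,
    phase_fragments,
)
from olcasm.read_simulator import simulate_genome
from olcasm.seqio import Read


def matrix_from_fragments(frags: dict[str, dict[int, int]], n_var: int) -> FragmentMatrix:
    positions = list(range(0, n_var * 100, 100))
    return FragmentMatrix(
        contig=0,
        positions=positions,
        alleles={p: "AC" for p in positions},
        fragments=frags,
    )


def brute_force_min_mec(frags: dict[str, dict[int, int]]) -> int:
    names = sorted(frags)
    best = None
    for bits in itertools.product((0, 1), repeat=len(names) - 1):
        assignment = {names[0]: 0}
        assignment.update({n: b for n, b in zip(names[1:], bits)})
        s = mec_score(frags, assignment)
        best = s if best is None else min(best, s)
    return best


class TestCallHetSites:
    def _aligned_column(self, bases):
        """Reads of length 21 all covering a contig, differing at pos 10."""
        contig = Contig("c", simulate_genome(1_000, 0.5, seed=110).sequence[:100])
        reads = {}
        alns = []
        for i, b in enumerate(bases):
            seq = list(contig.sequence[:21])
            seq[10] = b
            name = f"r{i}"
            reads[name] = Read(name, "".join(seq))
            alns.append(AlignmentRecord(name, 0, 0, [("=", 21)], False))
        return alns, [contig], reads

    def test_balanced_biallelic_column_is_het(self):
        alns, contigs, reads = self._aligned_column(["A"] * 15 + ["G"] * 15)
        sites = call_het_sites(alns, contigs, reads)
        assert any(s.pos == 10 and {s.allele0, s.allele1} == {"A", "G"} for s in sites)

    def test_unbalanced_column_not_het(self):
        alns, contigs, reads = self._aligned_column(["A"] * 29 + ["G"])
        sites = call_het_sites(alns, contigs, reads)
        assert not any(s.pos == 10 for s in sites)

    def test_low_depth_not_het(self):
        alns, contigs, reads = self._aligned_column(["A", "G", "A", "G"])
        assert call_het_sites(alns, contigs, reads) == []


class TestPhaseFragments:
    def test_two_perfect_complementary_pairs(self):
        frags = {
            "a": {0: 0, 1: 0, 2: 0},
            "b": {0: 0, 1: 0, 2: 0},
            "c": {0: 1, 1: 1, 2: 1},
            "d": {0: 1, 1: 1, 2: 1},
        }
        blocks = phase_fragments(matrix_from_fragments(frags, 3))
        assert len(blocks) == 1
        b = blocks[0]
        assert b.mec == 0
        assert b.assignment["a"] == b.assignment["b"]
        assert b.assignment["c"] == b.assignment["d"]
        assert b.assignment["a"] != b.assignment["c"]

    def test_single_fragment_block(self):
        blocks = phase_fragments(matrix_from_fragments({"a": {0: 0, 1: 1}}, 2))
        assert blocks[0].mec == 0

    def test_disconnected_variants_make_two_blocks(self):
        frags = {
            "a": {0: 0, 1: 0},
            "b": {0: 1, 1: 1},
            "c": {3: 0, 4: 0},
            "d": {3: 1, 4: 1},
        }
        blocks = phase_fragments(matrix_from_fragments(frags, 5))
        assert len(blocks) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_minimum_mec(self, seed):
        rng = np.random.default_rng(200 + seed)
        n_frag = int(rng.integers(4, 10))
        n_var = int(rng.integers(3, 7))
        truth = rng.integers(0, 2, n_var)
        frags = {}
        for i in range(n_frag):
            side = int(rng.integers(0, 2))
            lo = int(rng.integers(0, n_var - 2))
            hi = int(rng.integers(lo + 2, n_var + 1))
            alleles = {}
            for v in range(lo, hi):
                a = int(truth[v]) ^ side
                if rng.random() < 0.1:  # planted flip
                    a ^= 1
                alleles[v] = a
            frags[f"f{i}"] = alleles
        blocks = phase_fragments(matrix_from_fragments(frags, n_var))
        got = sum(b.mec for b in blocks)
        want = sum(
            brute_force_min_mec({n: frags[n] for n in b.fragments}) for b in blocks
        )
        assert got == want

    def test_haplotype_symmetry_under_allele_flip(self):
        rng = np.random.default_rng(210)
        frags = {
            f"f{i}": {v: int(rng.integers(0, 2)) for v in range(4)} for i in range(8)
        }
        b1 = phase_fragments(matrix_from_fragments(frags, 4))[0]
        flipped = {n: {v: a ^ 1 for v, a in f.items()} for n, f in frags.items()}
        b2 = phase_fragments(matrix_from_fragments(flipped, 4))[0]
        assert b1.mec == b2.mec
        same = all(b1.assignment[n] == b2.assignment[n] for n in frags)
        swapped = all(b1.assignment[n] != b2.assignment[n] for n in frags)
        assert same or swapped


class TestClassifyBlocks:
    def _block(self, frags):
        m = matrix_from_fragments(frags, 5)
        return m, phase_fragments(m)

    def test_balanced_block_phased(self):
        frags = {f"a{i}": {0: 0, 1: 0, 4: 0} for i in range(5)}
        frags.update({f"b{i}": {0: 1, 1: 1, 4: 1} for i in range(5)})
        m, blocks = self._block(frags)
        regions = classify_blocks(m, blocks, [], contig_len=500, mean_read_len=200)
        kinds = {r.kind for r in regions if r.block_index is not None}
        assert kinds == {"phased"}

    def test_hemizygous_block_flagged_deletion(self):
        # nearly all fragments on one side: a heterozygous deletion signature
        frags = {f"a{i}": {0: 0, 1: 0, 4: 0} for i in range(12)}
        frags["b0"] = {0: 1, 1: 1, 4: 1}
        m, blocks = self._block(frags)
        regions = classify_blocks(m, blocks, [], contig_len=500, mean_read_len=200)
        kinds = {r.kind for r in regions if r.block_index is not None}
        assert kinds == {"heterozygousDeletion"}

    def test_long_het_free_gap_is_homozygous(self):
        frags = {
            "a": {0: 0, 1: 0},
            "b": {0: 1, 1: 1},
            "c": {3: 0, 4: 0},
            "d": {3: 1, 4: 1},
        }
        m, blocks = self._block(frags)
        # variants at 0,100 then 300,400: the 200-bp gap > mean read length
        regions = classify_blocks(m, blocks, [], contig_len=500, mean_read_len=150)
        assert any(r.kind == "homozygous" for r in regions)

    def test_regions_tile_contig(self):
        frags = {f"a{i}": {0: 0, 1: 0, 4: 0} for i in range(5)}
        frags.update({f"b{i}": {0: 1, 1: 1, 4: 1} for i in range(5)})
        m, blocks = self._block(frags)
        regions = classify_blocks(m, blocks, [], contig_len=500, mean_read_len=200)
        regions.sort(key=lambda r: r.start)
        assert regions[0].start == 0 and regions[-1].end == 500
        for a, b in zip(regions, regions[1:]):
            assert a.end == b.start


class TestFragmentMatrix:
    def test_fragments_need_two_covered_variants(self):
        contig_seq = simulate_genome(1_000, 0.5, seed=111).sequence[:200]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
        sites = [
            HetSite(0, 50, contig_seq[50], alt[contig_seq[50]]),
            HetSite(0, 150, contig_seq[150], alt[contig_seq[150]]),
        ]
        reads = {
            "short": Read("short", contig_seq[40:70]),    # covers one site
            "long": Read("long", contig_seq[40:170]),     # covers both
        }
        alns = [
            AlignmentRecord("short", 0, 40, [("=", 30)], False),
            AlignmentRecord("long", 0, 40, [("=", 130)], False),
        ]
        fm = build_fragment_matrix(0, sites, alns, reads)
        assert "short" not in fm.fragments
        # the long read carries the contig (major) allele at both sites
        assert fm.fragments["long"] == {0: 0, 1: 0}
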