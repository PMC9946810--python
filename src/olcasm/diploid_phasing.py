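"""Haplotype-aware diploid assembly.

Heterozygous SNVs are called on the initial (collapsed) assembly, reads
become fragments over the het sites, and a max-cut-style heuristic
splits each connected fragment block into two haplotype clusters with a
low MEC (minimum error correction) score.  Blocks are then classified by
cluster depth into true phased regions, large heterozygous deletions, or
homozygous regions; edges that connect reads of different clusters
inside phased regions are removed from the original assembly graph and
layout + consensus are re-run to produce per-haplotype contigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from olcasm.consensus import (
    AlignmentRecord,
    Contig,
    _pileup,
    _ref_to_read_map,
    consensus_from_layout,
    oriented,
    polish,
    realign,
)
from olcasm.layout import build_layout, fit_distributions, select_safe_edges
from olcasm.pipeline import AssemblyResult, assemble
from olcasm.seqio import Read

logger = logging.getLogger("olcasm")

HET_MIN_DEPTH = 5
HET_MIN_FRACTION = 0.2
DELETION_DEPTH_RATIO = 0.25
_BASES = "ACGT"


@dataclass(frozen=True)
class HetSite:
    contig: int
    pos: int
    allele0: str  # major allele
    allele1: str


def call_het_sites(
    alignments: list[AlignmentRecord],
    contigs: list[Contig],
    reads: dict[str, Read],
    min_depth: int = HET_MIN_DEPTH,
    min_fraction: float = HET_MIN_FRACTION,
) -> list[HetSite]:
    """Pileup columns with a balanced second SNV allele.

    A column is heterozygous when depth >= min_depth and the second
    most frequent base holds a fraction in [min_fraction, 1-min_fraction].
    """
    by_contig: dict[int, list[AlignmentRecord]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig, []).append(a)
    sites: list[HetSite] = []
    for idx, contig in enumerate(contigs):
        alns = by_contig.get(idx, [])
        if not alns:
            continue
        bases, _, _ = _pileup(len(contig.sequence), alns, reads)
        depth = bases.sum(axis=1)
        order = np.argsort(bases, axis=1)
        top, second = order[:, -1], order[:, -2]
        cols = np.arange(len(contig.sequence))
        frac = np.where(depth > 0, bases[cols, second] / np.maximum(depth, 1), 0.0)
        het = (depth >= min_depth) & (frac >= min_fraction) & (frac <= 1 - min_fraction)
        for pos in np.flatnonzero(het):
            sites.append(
                HetSite(idx, int(pos), _BASES[top[pos]], _BASES[second[pos]])
            )
    return sites


@dataclass
class FragmentMatrix:
    """Sparse reads x het-variant allele matrix for one contig."""

    contig: int
    positions: list[int]  # het-site positions, ascending
    alleles: dict[int, str]  # pos -> (allele0, allele1) packed as 2 chars
    fragments: dict[str, dict[int, int]] = field(default_factory=dict)
    # read name -> {variant index -> allele in {0, 1}}


def build_fragment_matrix(
    contig_idx: int,
    sites: list[HetSite],
    alignments: list[AlignmentRecord],
    reads: dict[str, Read],
) -> FragmentMatrix:
    """Extract read alleles at het sites; fragments covering < 2 sites drop."""
    csites = sorted((s for s in sites if s.contig == contig_idx), key=lambda s: s.pos)
    positions = [s.pos for s in csites]
    fm = FragmentMatrix(
        contig=contig_idx,
        positions=positions,
        alleles={s.pos: s.allele0 + s.allele1 for s in csites},
    )
    pos_arr = np.array(positions, dtype=np.int64)
    for a in alignments:
        if a.contig != contig_idx:
            continue
        lo, hi = a.start, a.end
        i0, i1 = np.searchsorted(pos_arr, [lo, hi])
        if i1 - i0 < 2:
            continue
        r2r = _ref_to_read_map(a)
        seq = oriented(reads[a.read_name], a.reverse)
        frag: dict[int, int] = {}
        for vi in range(i0, i1):
            p = int(pos_arr[vi])
            ridx = r2r[p - a.start]
            if ridx < 0:
                continue
            base = seq[ridx]
            pair = fm.alleles[p]
            if base == pair[0]:
                frag[vi] = 0
            elif base == pair[1]:
                frag[vi] = 1
        if len(frag) >= 2:
            fm.fragments[a.read_name] = frag
    return fm


def mec_score(
    fragments: dict[str, dict[int, int]], assignment: dict[str, int]
) -> int:
    """MEC of a bipartition: per-variant per-cluster majority mismatches."""
    votes: dict[tuple[int, int], list[int]] = {}
    for name, frag in fragments.items():
        side = assignment[name]
        for vi, allele in frag.items():
            votes.setdefault((side, vi), []).append(allele)
    total = 0
    for alleles in votes.values():
        ones = sum(alleles)
        total += min(ones, len(alleles) - ones)
    return total


@dataclass
class PhasedBlock:
    variant_indices: list[int]
    fragments: list[str]
    assignment: dict[str, int]
    haplotypes: tuple[str, str]  # allele strings over the block's variants
    mec: int


def _connected_blocks(fragments: dict[str, dict[int, int]]) -> list[list[str]]:
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for frag in fragments.values():
        vis = list(frag)
        for v in vis[1:]:
            parent[find(vis[0])] = find(v)
    groups: dict[int, list[str]] = {}
    for name, frag in fragments.items():
        groups.setdefault(find(next(iter(frag))), []).append(name)
    return [sorted(g) for g in sorted(groups.values(), key=lambda g: g[0])]


def _local_search(
    names: list[str],
    fragments: dict[str, dict[int, int]],
    init: dict[str, int],
) -> tuple[dict[str, int], int]:
    """Single-fragment-flip descent on the MEC, with incremental updates.

    counts[(vi, side)] = [#allele-0, #allele-1] votes; a variant's MEC
    contribution is min(c0, c1) summed over the two sides, so flipping a
    fragment only touches the variants it covers.
    """
    assignment = dict(init)
    counts: dict[tuple[int, int], list[int]] = {}
    for n in names:
        side = assignment[n]
        for vi, al in fragments[n].items():
            counts.setdefault((vi, side), [0, 0])[al] += 1

    def contrib(vi: int, side: int) -> int:
        c = counts.get((vi, side))
        return min(c) if c else 0

    score = sum(min(c) for c in counts.values())
    improved = True
    while improved:
        improved = False
        for n in names:
            side = assignment[n]
            other = side ^ 1
            delta = 0
            for vi, al in fragments[n].items():
                before = contrib(vi, side) + contrib(vi, other)
                c_from = counts[(vi, side)]
                c_to = counts.setdefault((vi, other), [0, 0])
                c_from[al] -= 1
                c_to[al] += 1
                delta += contrib(vi, side) + contrib(vi, other) - before
            if delta < 0:
                assignment[n] = other
                score += delta
                improved = True
            else:  # revert
                for vi, al in fragments[n].items():
                    counts[(vi, other)][al] -= 1
                    counts[(vi, side)][al] += 1
    return assignment, score


def phase_fragments(
    matrix: FragmentMatrix, seed: int = 17, restarts: int = 32
) -> list[PhasedBlock]:
    """Split each connected fragment block into two haplotype clusters.

    Randomized max-cut-style improvement: random bipartitions refined by
    single-fragment flips until no flip lowers the MEC, best of
    `restarts` restarts (fixed seed, deterministic).
    """
    rng = np.random.default_rng(seed)
    blocks: list[PhasedBlock] = []
    for names in _connected_blocks(matrix.fragments):
        frags = {n: matrix.fragments[n] for n in names}
        if len(names) == 1:
            best_assign, best = {names[0]: 0}, 0
        else:
            best_assign, best = None, None
            for r in range(restarts):
                if r == 0:
                    init = {n: 0 for n in names}
                    init[names[0]] = 0
                    # seed greedy: anchor first fragment, others by agreement
                    anchor = frags[names[0]]
                    for n in names[1:]:
                        agree = sum(
                            1 for vi, al in frags[n].items()
                            if vi in anchor and anchor[vi] == al
                        )
                        disagree = sum(
                            1 for vi, al in frags[n].items()
                            if vi in anchor and anchor[vi] != al
                        )
                        init[n] = 0 if agree >= disagree else 1
                else:
                    init = {n: int(rng.integers(0, 2)) for n in names}
                assign, score = _local_search(names, frags, init)
                if best is None or score < best:
                    best, best_assign = score, assign
                if best == 0:
                    break
        vis = sorted({vi for n in names for vi in matrix.fragments[n]})
        haps = _block_haplotypes(frags, best_assign, vis, matrix)
        blocks.append(
            PhasedBlock(
                variant_indices=vis,
                fragments=names,
                assignment=best_assign,
                haplotypes=haps,
                mec=int(best),
            )
        )
    return blocks


def _block_haplotypes(
    frags: dict[str, dict[int, int]],
    assignment: dict[str, int],
    vis: list[int],
    matrix: FragmentMatrix,
) -> tuple[str, str]:
    haps = []
    for side in (0, 1):
        out = []
        for vi in vis:
            alleles = [
                frag[vi]
                for n, frag in frags.items()
                if assignment[n] == side and vi in frag
            ]
            if not alleles:
                out.append("-")
                continue
            ones = sum(alleles)
            bit = 1 if ones * 2 > len(alleles) else 0
            pair = matrix.alleles[matrix.positions[vi]]
            out.append(pair[bit])
        haps.append("".join(out))
    return haps[0], haps[1]


@dataclass
class BlockRegion:
    start: int
    end: int
    kind: str  # phased | heterozygousDeletion | homozygous
    block_index: int | None = None


def classify_blocks(
    matrix: FragmentMatrix,
    blocks: list[PhasedBlock],
    alignments: list[AlignmentRecord],
    contig_len: int,
    mean_read_len: float,
) -> list[BlockRegion]:
    """Tile the contig into phased / het-deletion / homozygous regions.

    A het block whose two clusters both carry >= 25% of the local depth
    is a true phased region; a block where one cluster falls below 25%
    of the other is a heterozygous deletion.  Gaps longer than the mean
    read length with no het sites are homozygous; shorter gaps are
    absorbed by extending the neighbouring blocks to their midpoint.
    """
    spans: list[tuple[int, int, str, int]] = []
    for bi, b in enumerate(blocks):
        if not b.variant_indices:
            continue
        s = matrix.positions[b.variant_indices[0]]
        e = matrix.positions[b.variant_indices[-1]] + 1
        d0 = sum(1 for n in b.fragments if b.assignment[n] == 0)
        d1 = sum(1 for n in b.fragments if b.assignment[n] == 1)
        lo, hi = min(d0, d1), max(d0, d1)
        kind = "phased" if hi == 0 or lo >= DELETION_DEPTH_RATIO * hi else "heterozygousDeletion"
        spans.append((s, e, kind, bi))
    spans.sort()
    regions: list[BlockRegion] = []
    cursor = 0
    for s, e, kind, bi in spans:
        gap = s - cursor
        if gap > 0:
            if gap > mean_read_len:
                regions.append(BlockRegion(cursor, s, "homozygous"))
                start = s
            else:
                # absorb a short gap: previous block extends to the midpoint
                mid = cursor if not regions else (cursor + s) // 2
                if regions:
                    regions[-1].end = mid
                start = mid if regions else 0
        else:
            start = cursor
        regions.append(BlockRegion(start, e, kind, bi))
        cursor = e
    if cursor < contig_len:
        tail = contig_len - cursor
        if regions and tail <= mean_read_len:
            regions[-1].end = contig_len
        else:
            regions.append(BlockRegion(cursor, contig_len, "homozygous"))
    if not regions:
        regions.append(BlockRegion(0, contig_len, "homozygous"))
    return regions


@dataclass
class DiploidResult:
    contigs: list[Contig]
    haploid: AssemblyResult
    het_sites: list[HetSite]
    matrices: list[FragmentMatrix]
    blocks: dict[int, list[PhasedBlock]]  # contig -> blocks
    regions: dict[int, list[BlockRegion]]
    assignment: dict[str, tuple[int, int, int]]  # read -> (contig, block, cluster)
    contig_tags: list[str]  # FASTA-header provenance per output contig


def assemble_diploid(
    reads: list[Read],
    k: int = 25,
    w: int = 40,
    seed: int = 17,
) -> DiploidResult:
    """Phasing-aware assembly: haploid pass, phase, cut graph, re-layout."""
    haploid = assemble(reads, k=k, w=w)
    read_map = haploid.graph.reads
    het = call_het_sites(haploid.alignments, haploid.contigs, read_map)
    matrices: list[FragmentMatrix] = []
    blocks: dict[int, list[PhasedBlock]] = {}
    regions: dict[int, list[BlockRegion]] = {}
    assignment: dict[str, tuple[int, int, int]] = {}
    mean_read_len = float(np.mean([len(r) for r in reads])) if reads else 0.0
    aln_by_read = {a.read_name: a for a in haploid.alignments}
    if not het:
        logger.info("no heterozygous site called; diploid output equals haploid")
        return DiploidResult(
            haploid.contigs, haploid, [], [], {}, {}, {},
            [c.name for c in haploid.contigs],
        )
    for ci in range(len(haploid.contigs)):
        fm = build_fragment_matrix(ci, het, haploid.alignments, read_map)
        matrices.append(fm)
        if not fm.fragments:
            continue
        bl = phase_fragments(fm, seed=seed)
        blocks[ci] = bl
        regions[ci] = classify_blocks(
            fm, bl, haploid.alignments, len(haploid.contigs[ci].sequence), mean_read_len
        )
        for bi, b in enumerate(bl):
            for name in b.fragments:
                assignment[name] = (ci, bi, b.assignment[name])

    phased_regions = {
        ci: [(r.start, r.end) for r in regs if r.kind == "phased"]
        for ci, regs in regions.items()
    }

    def in_phased(name: str) -> bool:
        a = aln_by_read.get(name)
        if a is None:
            return False
        for s, e in phased_regions.get(a.contig, []):
            if a.start < e and a.end > s:
                return True
        return False

    graph = haploid.graph
    removed = 0
    kept_edges = []
    for e in graph.edges:
        ra, rb = e.u[0], e.v[0]
        ta, tb = assignment.get(ra), assignment.get(rb)
        if (
            ta is not None
            and tb is not None
            and ta[:2] == tb[:2]
            and ta[2] != tb[2]
            and in_phased(ra)
            and in_phased(rb)
        ):
            removed += 1
            continue
        kept_edges.append(e)
    logger.info("diploid: removed %d cross-haplotype edges", removed)
    graph.edges = kept_edges
    for e in graph.edges:
        e.safe = False
        e.log_likelihood = None
    graph.finalize()
    safe = select_safe_edges(graph)
    model = fit_distributions([graph.edges[i] for i in safe])
    layout = build_layout(graph, safe, model)
    contigs, placements = consensus_from_layout(graph, layout)

    # tag each new contig with the majority haplotype of its reads and
    # polish it with same-cluster (or unassigned) reads only
    contig_cluster: dict[int, tuple[int, int, int] | None] = {}
    reads_of_contig: dict[int, list] = {}
    for p in placements:
        reads_of_contig.setdefault(p.contig, []).append(p)
    tags: list[str] = []
    for ci, contig in enumerate(contigs):
        tallies: dict[tuple[int, int, int], int] = {}
        for p in reads_of_contig.get(ci, []):
            t = assignment.get(p.read_name)
            if t is not None:
                tallies[t] = tallies.get(t, 0) + 1
        if tallies:
            tag_key = max(tallies, key=lambda t: (tallies[t], -t[2]))
            contig_cluster[ci] = tag_key
            tags.append(f"{contig.name} block={tag_key[0]}.{tag_key[1]} hap={tag_key[2] + 1}")
        else:
            contig_cluster[ci] = None
            tags.append(contig.name)
    filtered = [
        p for p in placements
        if _cluster_compatible(assignment.get(p.read_name), contig_cluster[p.contig])
    ]
    alignments = realign(contigs, filtered, read_map)
    contigs = polish(contigs, alignments, read_map)
    return DiploidResult(
        contigs=contigs,
        haploid=haploid,
        het_sites=het,
        matrices=matrices,
        blocks=blocks,
        regions=regions,
        assignment=assignment,
        contig_tags=tags,
    )


def write_het_vcf(result: DiploidResult, contigs: list[Contig], path) -> None:
    """Minimal single-sample VCF-dialect dump of the called het sites.

    Positions are 1-based; genotypes are phased `0|1` inside blocks.
    Major allele is REF (matching the initial-assembly consensus base).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c.name},length={len(c.sequence)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for s in result.het_sites:
            name = contigs[s.contig].name
            fh.write(
                f"{name}\t{s.pos + 1}\t.\t{s.allele0}\t{s.allele1}\t.\tPASS\t.\tGT\t0|1\n"
            )


def _cluster_compatible(
    read_tag: tuple[int, int, int] | None, contig_tag: tuple[int, int, int] | None
) -> bool:
    if read_tag is None or contig_tag is None:
        return True
    if read_tag[:2] != contig_tag[:2]:
        return True
    return read_tag[2] == contig_tag[2]
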