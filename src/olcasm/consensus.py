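"""Consensus construction along layout paths, read-to-contig realignment,
pileup + active-region polishing, and contig circularization.

The initial consensus concatenates oriented path reads: at each junction
the next read is dovetail-aligned to the consensus end to recompute the
true overlap and only its overhang is appended.  Polishing then realigns
every read to its contig, applies per-column majority bases (pass 1) and
locally reassembles "active regions" -- intervals where every base lies
within 5 bp of an indel call -- with a small de Bruijn graph (pass 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from olcasm._align import glocal_align, overlap_align
from olcasm.layout import Layout
from olcasm.overlap_graph import AssemblyGraph
from olcasm.seqio import Read, reverse_complement, seq_to_codes

MIN_JUNCTION_IDENTITY = 0.65
OVERLAP_SLACK = 500  # dovetail search window beyond the predicted overlap
INDEL_SUPPORT = 2
DILATION = 5
FLANK = 20
MINI_K = 15


@dataclass
class Contig:
    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Placement:
    """Approximate position of a read on a contig from the layout."""

    read_name: str
    contig: int
    start: int
    reverse: bool


@dataclass
class AlignmentRecord:
    read_name: str
    contig: int
    start: int  # 0-based on the contig
    ops: list[tuple[str, int]]  # op in {"=", "X", "I", "D"} (or "M")
    reverse: bool
    edit_distance: int = 0

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.ops if op in ("=", "X", "M", "D"))

    @property
    def end(self) -> int:
        return self.start + self.ref_span


def oriented(read: Read, reverse: bool) -> str:
    return reverse_complement(read.sequence) if reverse else read.sequence


def build_path_consensus(
    path: list[tuple[str, bool]],
    edges,
    reads: dict[str, Read],
) -> list[tuple[str, list[Placement]]]:
    """Consensus of one layout path; may split on a failed junction.

    Returns a list of (sequence, placements); a junction whose dovetail
    identity falls below 65% splits the path into two contigs.
    """
    first, frev = path[0]
    seq = oriented(reads[first], frev)
    pieces: list[tuple[str, list[Placement]]] = []
    placements = [Placement(first, 0, 0, frev)]
    for step, (name, rev) in enumerate(path[1:]):
        read_seq = oriented(reads[name], rev)
        predicted = int(edges[step].overlap) if step < len(edges) else 0
        window = predicted + OVERLAP_SLACK
        tail = seq[-min(len(seq), window):]
        prefix = read_seq[: min(len(read_seq), window)]
        identity, true_ov = overlap_align(tail, prefix)
        if true_ov <= 0 or identity < MIN_JUNCTION_IDENTITY:
            pieces.append((seq, placements))
            seq = read_seq
            placements = [Placement(name, 0, 0, rev)]
            continue
        placements.append(Placement(name, 0, len(seq) - true_ov, rev))
        seq = seq + read_seq[true_ov:]
    pieces.append((seq, placements))
    return pieces


def consensus_from_layout(
    graph: AssemblyGraph, layout: Layout, name_prefix: str = "contig"
) -> tuple[list[Contig], list[Placement]]:
    """All path consensi plus placements of path AND embedded reads."""
    contigs: list[Contig] = []
    placements: list[Placement] = []
    for path, edges in zip(layout.paths, layout.path_edges):
        for seq, place in build_path_consensus(path, edges, graph.reads):
            idx = len(contigs)
            contigs.append(Contig(f"{name_prefix}_{idx + 1}", seq))
            for p in place:
                p.contig = idx
                placements.append(p)
    by_read = {p.read_name: p for p in placements}
    for name, host, rel_start, rel_rev in graph.embedded:
        hp = by_read.get(host)
        if hp is None:
            continue
        host_len = len(graph.reads[host])
        rlen = len(graph.reads[name])
        if not hp.reverse:
            start = hp.start + rel_start
        else:
            start = hp.start + host_len - rel_start - rlen
        placements.append(Placement(name, hp.contig, max(0, start), hp.reverse != rel_rev))
    return contigs, placements


def _edlib_containment(
    probe: str, contigs: list[Contig], hosts: list[int], max_error: float = 0.3
) -> tuple[int, int, bool] | None:
    """Best infix placement of a short probe inside one of the hosts."""
    import edlib

    best: tuple[float, int, int, bool] | None = None
    for j in hosts:
        target = contigs[j].sequence
        for reverse, seq in ((False, probe), (True, reverse_complement(probe))):
            res = edlib.align(seq, target, mode="HW", task="locations")
            d = res["editDistance"]
            if d < 0 or d / len(probe) > max_error:
                continue
            if best is None or d / len(probe) < best[0]:
                best = (d / len(probe), j, res["locations"][0][0], reverse)
    if best is None:
        return None
    return best[1], best[2], best[3]


def rescue_unplaced(
    contigs: list[Contig],
    placements: list[Placement],
    reads: dict[str, Read],
    k: int = 25,
    w: int = 40,
    min_score: int = 5,
) -> tuple[list[Contig], list[Placement]]:
    """Absorb contigs contained in longer contigs.

    Containments that go undetected during graph construction (sequencing
    errors can break the minimizer evidence) leave singleton paths or
    short redundant paths whose consensus lies entirely inside another
    contig.  Each contig is aligned against the strictly longer ones;
    contained contigs are dropped and their reads re-placed on the host,
    mirroring the recovery of embedded reads.
    """
    from olcasm.kmer_spectrum import RankModel, build_spectrum
    from olcasm.minimizer_index import align_read, build_table

    tol = 2 * k
    order = sorted(range(len(contigs)), key=lambda i: len(contigs[i].sequence))
    dropped: dict[int, tuple[int, int, bool]] = {}  # contig -> (host, start, reverse)
    for ci in order:
        hosts = [
            j for j in range(len(contigs))
            if j not in dropped and j != ci
            and len(contigs[j].sequence) > len(contigs[ci].sequence)
        ]
        if not hosts:
            continue
        refs = [Read(str(j), contigs[j].sequence) for j in hosts]
        try:
            spec = build_spectrum(refs)
        except ValueError:
            continue
        model = RankModel.from_spectrum(spec)
        table = build_table(refs, k=k, w=w, spec=spec, model=model)
        probe = Read(f"probe_{ci}", contigs[ci].sequence)
        hit = align_read(table, probe, spec, model)
        placed = None  # (host, start, reverse)
        if hit.contig is not None and hit.score >= min_score:
            host = int(hit.contig)
            if (
                hit.start >= -tol
                and hit.start + len(probe) <= len(contigs[host].sequence) + tol
            ):
                placed = (host, max(0, hit.start), hit.reverse)
        if placed is None and len(probe) <= 5_000:
            # short probes can lack minimizer evidence; fall back to a
            # direct infix edit-distance scan against each host
            placed = _edlib_containment(probe.sequence, contigs, hosts)
        if placed is not None:
            dropped[ci] = placed
    if not dropped:
        return contigs, placements

    def resolve(ci: int, start: int, reverse: bool, length: int) -> tuple[int, int, bool]:
        """Follow host chains until a surviving contig is reached."""
        while ci in dropped:
            host, hstart, hrev = dropped[ci]
            clen = len(contigs[ci].sequence)
            if hrev:
                start = hstart + clen - start - length
                reverse = not reverse
            else:
                start = hstart + start
            ci = host
        return ci, start, reverse

    remap: dict[int, int] = {}
    new_contigs: list[Contig] = []
    for i, c in enumerate(contigs):
        if i in dropped:
            continue
        remap[i] = len(new_contigs)
        new_contigs.append(Contig(f"contig_{len(new_contigs) + 1}", c.sequence))
    new_placements: list[Placement] = []
    for p in placements:
        rlen = len(reads[p.read_name]) if p.read_name in reads else 0
        ci, start, reverse = resolve(p.contig, p.start, p.reverse, rlen)
        new_placements.append(
            Placement(p.read_name, remap[ci], max(0, start), reverse)
        )
    return new_contigs, new_placements


def merge_overlapping_contigs(
    contigs: list[Contig],
    placements: list[Placement],
    reads: dict[str, Read],
    k: int = 25,
    w: int = 40,
    min_score: int = 5,
    max_rounds: int = 10,
) -> tuple[list[Contig], list[Placement]]:
    """Join contigs whose ends dovetail.

    Greedy edge selection can strand two paths that overlap at their
    ends (the connecting edges all touched already-matched vertices).
    Each contig is mapped against the longer contigs; a placement that
    hangs over a host end is confirmed with the dovetail aligner and the
    contigs are merged, with read placements carried across.
    """
    from olcasm.kmer_spectrum import RankModel, build_spectrum
    from olcasm.minimizer_index import align_read, build_table

    tol = 2 * k
    for _ in range(max_rounds):
        if len(contigs) < 2:
            break
        merged_this_round = False
        order = sorted(range(len(contigs)), key=lambda i: len(contigs[i].sequence))
        for ci in order:
            probe = contigs[ci].sequence
            hosts = [
                j for j in range(len(contigs))
                if j != ci and len(contigs[j].sequence) >= len(probe)
            ]
            if not hosts:
                continue
            refs = [Read(str(j), contigs[j].sequence) for j in hosts]
            try:
                spec = build_spectrum(refs)
            except ValueError:
                continue
            model = RankModel.from_spectrum(spec)
            table = build_table(refs, k=k, w=w, spec=spec, model=model)
            hit = align_read(table, Read(f"probe_{ci}", probe), spec, model)
            if hit.contig is None or hit.score < min_score:
                continue
            host = int(hit.contig)
            host_seq = contigs[host].sequence
            Lh, Lp = len(host_seq), len(probe)
            s = hit.start
            if s >= -tol and s + Lp <= Lh + tol:
                continue  # containment; the rescue pass owns this case
            probe_or = reverse_complement(probe) if hit.reverse else probe

            def orient(p: Placement) -> tuple[int, bool]:
                if hit.reverse:
                    rlen = len(reads[p.read_name]) if p.read_name in reads else 0
                    return Lp - p.start - rlen, not p.reverse
                return p.start, p.reverse

            merged_seq = None
            if tol < s < Lh:
                # probe extends past the host's right end
                ov_pred = Lh - s
                window = ov_pred + OVERLAP_SLACK
                identity, ov = overlap_align(
                    host_seq[-min(Lh, window):], probe_or[: min(Lp, window)]
                )
                if ov >= 64 and identity >= MIN_JUNCTION_IDENTITY:
                    merged_seq = host_seq + probe_or[ov:]
                    host_shift, probe_shift = 0, Lh - ov
            elif s < -tol and s + Lp > tol:
                # probe extends past the host's left end
                ov_pred = Lp + s
                window = ov_pred + OVERLAP_SLACK
                identity, ov = overlap_align(
                    probe_or[-min(Lp, window):], host_seq[: min(Lh, window)]
                )
                if ov >= 64 and identity >= MIN_JUNCTION_IDENTITY:
                    merged_seq = probe_or + host_seq[ov:]
                    host_shift, probe_shift = Lp - ov, 0
            if merged_seq is None:
                continue
            new_contigs: list[Contig] = []
            remap: dict[int, int] = {}
            for j, c in enumerate(contigs):
                if j in (ci, host):
                    continue
                remap[j] = len(new_contigs)
                new_contigs.append(c)
            merged_idx = len(new_contigs)
            new_contigs.append(Contig("merged", merged_seq))
            new_placements: list[Placement] = []
            for p in placements:
                if p.contig == host:
                    new_placements.append(
                        Placement(p.read_name, merged_idx, p.start + host_shift, p.reverse)
                    )
                elif p.contig == ci:
                    start, reverse = orient(p)
                    new_placements.append(
                        Placement(p.read_name, merged_idx,
                                  max(0, start + probe_shift), reverse)
                    )
                else:
                    new_placements.append(
                        Placement(p.read_name, remap[p.contig], p.start, p.reverse)
                    )
            contigs, placements = new_contigs, new_placements
            merged_this_round = True
            break
        if not merged_this_round:
            break
    renamed = [Contig(f"contig_{i + 1}", c.sequence) for i, c in enumerate(contigs)]
    return renamed, placements


def realign(
    contigs: list[Contig],
    placements: list[Placement],
    reads: dict[str, Read],
    max_error: float = 0.35,
) -> list[AlignmentRecord]:
    """Banded realignment of each read around its layout position."""
    out: list[AlignmentRecord] = []
    for p in placements:
        read = reads.get(p.read_name)
        if read is None:
            continue
        seq = oriented(read, p.reverse)
        contig = contigs[p.contig].sequence
        pad = 150 + len(seq) // 20
        lo = max(0, p.start - pad)
        hi = min(len(contig), p.start + len(seq) + pad)
        window = contig[lo:hi]
        if len(window) < len(seq) // 2:
            continue
        res = glocal_align(seq, window)
        if res is None:
            continue
        dist, offset, ops = res
        if dist > max_error * len(seq):
            continue
        out.append(AlignmentRecord(p.read_name, p.contig, lo + offset, ops, p.reverse, dist))
    out.sort(key=lambda a: (a.contig, a.start, a.read_name))
    return out


def _pileup(
    contig_len: int, alignments: list[AlignmentRecord], reads: dict[str, Read]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(base counts [L,4], deletion-call counts [L], insertion-call counts [L])."""
    bases = np.zeros((contig_len, 4), dtype=np.int32)
    dels = np.zeros(contig_len, dtype=np.int32)
    ins = np.zeros(contig_len, dtype=np.int32)
    for a in alignments:
        codes = seq_to_codes(oriented(reads[a.read_name], a.reverse))
        rpos, cpos = 0, a.start
        for op, n in a.ops:
            if op in ("=", "X", "M"):
                seg = codes[rpos : rpos + n]
                idx = np.arange(cpos, cpos + n)
                keep = seg != 255
                np.add.at(bases, (idx[keep], seg[keep]), 1)
                rpos += n
                cpos += n
            elif op == "I":
                if cpos < contig_len:
                    ins[cpos] += 1
                rpos += n
            elif op == "D":
                dels[cpos : cpos + n] += 1
                cpos += n
    return bases, dels, ins


def _ref_to_read_map(a: AlignmentRecord) -> np.ndarray:
    """Read index consuming each contig position of the alignment (-1 = deleted)."""
    out = np.full(a.ref_span, -1, dtype=np.int32)
    rpos, c = 0, 0
    for op, n in a.ops:
        if op in ("=", "X", "M"):
            out[c : c + n] = np.arange(rpos, rpos + n)
            rpos += n
            c += n
        elif op == "I":
            rpos += n
        elif op == "D":
            c += n
    return out


def detect_active_regions(
    indel_positions: np.ndarray, contig_len: int, dilation: int = DILATION
) -> list[tuple[int, int]]:
    """Dilate indel-call positions by +-dilation bp and merge intervals."""
    if len(indel_positions) == 0:
        return []
    regions: list[tuple[int, int]] = []
    for p in np.sort(np.asarray(indel_positions)):
        s, e = max(0, int(p) - dilation), min(contig_len, int(p) + dilation + 1)
        if regions and s <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], e))
        else:
            regions.append((s, e))
    return regions


def _majority_pass(seq: str, bases: np.ndarray) -> str:
    """Replace each consensus base by the pileup majority; ties keep it."""
    codes = seq_to_codes(seq)
    maj = bases.argmax(axis=1)
    maj_count = bases.max(axis=1)
    cur = np.where(codes == 255, 0, codes)
    cur_count = bases[np.arange(len(seq)), cur]
    cur_count = np.where(codes == 255, -1, cur_count)
    replace = maj_count > cur_count
    new_codes = np.where(replace, maj, codes)
    lut = np.array(list("ACGT"), dtype="U1")
    out = np.where(new_codes == 255, "N", lut[np.minimum(new_codes, 3)])
    return "".join(out.tolist())


def _heaviest_debruijn_path(
    segments: list[str], anchor_left: str, anchor_right: str, max_len: int
) -> str | None:
    """Heaviest anchor-to-anchor path in the segment de Bruijn graph.

    Nodes are 15-mers, edge weights are transition multiplicities; cycles
    reachable between the anchors abort the fix (DAG-restricted search).
    """
    adj: dict[str, dict[str, int]] = {}
    for seg in segments:
        for i in range(len(seg) - MINI_K):
            u = seg[i : i + MINI_K]
            v = seg[i + 1 : i + 1 + MINI_K]
            adj.setdefault(u, {})
            adj[u][v] = adj[u].get(v, 0) + 1
    if anchor_left not in adj and anchor_left != anchor_right:
        return None
    # Kahn topological sort on nodes reachable from the left anchor
    reach: set[str] = set()
    stack = [anchor_left]
    while stack:
        u = stack.pop()
        if u in reach:
            continue
        reach.add(u)
        stack.extend(adj.get(u, {}))
    indeg = {u: 0 for u in reach}
    for u in reach:
        for v in adj.get(u, {}):
            if v in reach:
                indeg[v] += 1
    queue = [u for u, d in indeg.items() if d == 0]
    topo: list[str] = []
    while queue:
        u = queue.pop()
        topo.append(u)
        for v in adj.get(u, {}):
            if v in reach:
                indeg[v] -= 1
                if indeg[v] == 0:
                    queue.append(v)
    if len(topo) != len(reach):
        return None  # cycle
    best: dict[str, float] = {anchor_left: 0.0}
    back: dict[str, str] = {}
    for u in topo:
        if u not in best:
            continue
        for v, wgt in adj.get(u, {}).items():
            if v in reach and best[u] + wgt > best.get(v, -1.0):
                best[v] = best[u] + wgt
                back[v] = u
    if anchor_right not in best:
        return None
    node = anchor_right
    rev_path = [node]
    while node != anchor_left:
        node = back[node]
        rev_path.append(node)
    kmers = rev_path[::-1]
    spelled = kmers[0] + "".join(km[-1] for km in kmers[1:])
    if len(spelled) > max_len:
        return None
    return spelled


def _pick_anchor(
    consensus: str, segments: list[str], start: int, inward: bool, limit: int
) -> tuple[int, str] | None:
    """First consensus 15-mer near `start` present in >=50% of segments."""
    need = max(1, (len(segments) + 1) // 2)
    for off in range(0, 8):
        pos = start + off if inward else start - off
        if pos < 0 or pos + MINI_K > len(consensus):
            continue
        if inward and pos + MINI_K > limit:
            break
        if not inward and pos < limit:
            break
        kmer = consensus[pos : pos + MINI_K]
        if sum(kmer in s for s in segments) >= need:
            return pos, kmer
    return None


def polish(
    contigs: list[Contig],
    alignments: list[AlignmentRecord],
    reads: dict[str, Read],
) -> list[Contig]:
    """Two-pass polishing: pileup majority, then active-region reassembly."""
    by_contig: dict[int, list[AlignmentRecord]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig, []).append(a)
    out: list[Contig] = []
    for idx, contig in enumerate(contigs):
        alns = by_contig.get(idx, [])
        if not alns:
            out.append(contig)
            continue
        L = len(contig.sequence)
        bases, dels, ins = _pileup(L, alns, reads)
        seq = _majority_pass(contig.sequence, bases)
        calls = np.flatnonzero((dels >= INDEL_SUPPORT) | (ins >= INDEL_SUPPORT))
        regions = detect_active_regions(calls, L)
        replacements: list[tuple[int, int, str]] = []
        for s, e in regions:
            wlo, whi = max(0, s - FLANK), min(L, e + FLANK)
            segments = _region_segments(alns, reads, wlo, whi)
            if len(segments) < INDEL_SUPPORT:
                continue
            left = _pick_anchor(seq, segments, wlo, inward=True, limit=s)
            right = _pick_anchor(seq, segments, whi - MINI_K, inward=False, limit=e)
            if left is None or right is None or right[0] <= left[0]:
                continue
            spelled = _heaviest_debruijn_path(
                segments, left[1], right[1], max_len=4 * (whi - wlo)
            )
            if spelled is None:
                continue
            replacements.append((left[0], right[0] + MINI_K, spelled))
        for s, e, spelled in sorted(replacements, reverse=True):
            seq = seq[:s] + spelled + seq[e:]
        out.append(Contig(contig.name, seq))
    return out


def _region_segments(
    alns: list[AlignmentRecord],
    reads: dict[str, Read],
    lo: int,
    hi: int,
) -> list[str]:
    """Read subsequences aligned across contig interval [lo, hi)."""
    segments: list[str] = []
    for a in alns:
        if a.start > lo or a.end < hi:
            continue
        r2r = _ref_to_read_map(a)
        window = r2r[lo - a.start : hi - a.start]
        covered = window[window >= 0]
        if covered.size < MINI_K:
            continue
        seq = oriented(reads[a.read_name], a.reverse)
        segments.append(seq[int(covered.min()) : int(covered.max()) + 1])
    return segments


def circularize(contigs: list[Contig], origins: list[Read], min_score: int = 5) -> list[Contig]:
    """Rotate/orient contigs so the best-matching origin starts at 0."""
    from olcasm.kmer_spectrum import RankModel, build_spectrum
    from olcasm.minimizer_index import REFERENCE_MAX_FREQUENCY, align_read, build_table

    out = list(contigs)
    for origin in origins:
        refs = [Read(c.name, c.sequence) for c in out]
        try:
            spec = build_spectrum(refs)
        except ValueError:
            return out
        model = RankModel.from_spectrum(spec)
        table = build_table(refs, k=25, w=40, spec=spec, model=model,
                            max_frequency=REFERENCE_MAX_FREQUENCY)
        hit = align_read(table, origin, spec, model)
        if hit.contig is None or hit.score < min_score:
            continue
        idx = next(i for i, c in enumerate(out) if c.name == hit.contig)
        seq = out[idx].sequence
        if hit.reverse:
            seq = reverse_complement(seq)
            table2 = build_table([Read("rc", seq)], k=25, w=40, spec=spec, model=model,
                                 max_frequency=REFERENCE_MAX_FREQUENCY)
            hit2 = align_read(table2, origin, spec, model)
            if hit2.contig is None:
                continue
            p = hit2.start
        else:
            p = hit.start
        p = max(0, min(len(seq) - 1, p))
        out[idx] = Contig(out[idx].name, seq[p:] + seq[:p])
    return out
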