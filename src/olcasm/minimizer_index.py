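"""Minimizer selection with the rank-based hash, the minimizer table, and
the minimizer-based reference aligner.

Minimizers are strand-symmetric: both the forward and reverse-complement
code of every k-mer are hashed and the orientation with the smaller hash
(ties: smaller code) represents the k-mer, so two reads sequenced from
opposite strands of the same locus select the same minimizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from olcasm.kmer_spectrum import RankModel, Spectrum15, hash_codes, kmer_codes, revcomp_codes
from olcasm.seqio import Read

DEFAULT_K = 25
DEFAULT_W = 40
REFERENCE_MAX_FREQUENCY = 1000

_SENTINEL = np.int64(1) << 62


@dataclass(frozen=True)
class Minimizer:
    code: int
    hash: int
    pos: int
    reverse: bool


def _minimizer_arrays(
    seq: str, k: int, w: int, spec: Spectrum15, model: RankModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(pos, code, hash, reverse) arrays of the selected minimizers.

    Standard w-window argmin over hash values; ranks built from
    (hash, code, position) so ties are broken deterministically by
    smaller code, then smaller position.
    """
    empty = (
        np.empty(0, np.int64),
        np.empty(0, np.uint64),
        np.empty(0, np.int64),
        np.empty(0, bool),
    )
    if len(seq) < k + w - 1:
        return empty
    codes_f, valid = kmer_codes(seq, k)
    m = codes_f.size
    if m < w or not valid.any():
        return empty
    codes_r = revcomp_codes(codes_f, k)
    h_f = hash_codes(codes_f, k, spec, model)
    h_r = hash_codes(codes_r, k, spec, model)
    rev = (h_r < h_f) | ((h_r == h_f) & (codes_r < codes_f))
    h = np.where(rev, h_r, h_f)
    code = np.where(rev, codes_r, codes_f)
    # unique rank per position honoring (hash, code, pos) ordering
    order = np.lexsort((np.arange(m), code, h))
    ranks = np.empty(m, dtype=np.int64)
    ranks[order] = np.arange(m)
    ranks[~valid] = _SENTINEL
    windows = np.lib.stride_tricks.sliding_window_view(ranks, w)
    argmins = windows.argmin(axis=1) + np.arange(m - w + 1)
    sel = np.unique(argmins)
    sel = sel[valid[sel]]
    return sel, code[sel], h[sel], rev[sel]


def compute_minimizers(
    read: Read, k: int, w: int, spec: Spectrum15, model: RankModel | None = None
) -> list[Minimizer]:
    """Minimizers of one read (the minimum-hash k-mer of every window)."""
    if not 15 <= k <= 31:
        raise ValueError("k must be in [15, 31]")
    if w < 1:
        raise ValueError("w must be >= 1")
    if model is None:
        model = RankModel.from_spectrum(spec)
    pos, code, h, rev = _minimizer_arrays(read.sequence, k, w, spec, model)
    return [
        Minimizer(int(c), int(hh), int(p), bool(r))
        for p, c, hh, r in zip(pos, code, h, rev)
    ]


@dataclass
class MinimizerTable:
    """Selected-code -> [(sequence index, position, reverse)] lookup.

    Keyed by the selected k-mer code (selection already happened through
    the hash), which keeps hash collisions between distinct k-mers from
    producing spurious hits.  Codes occurring `max_frequency` or more
    times are purged (reference-aligner mode uses 1,000).
    """

    k: int
    w: int
    seq_names: list[str]
    seq_lengths: list[int]
    entries: dict[int, list[tuple[int, int, bool]]] = field(default_factory=dict)
    max_frequency: int | None = None

    def add_sequence(self, idx: int, pos, code, rev) -> None:
        entries = self.entries
        for p, c, r in zip(pos.tolist(), code.tolist(), rev.tolist()):
            entries.setdefault(c, []).append((idx, p, r))

    def purge_frequent(self) -> None:
        if self.max_frequency is None:
            return
        drop = [c for c, lst in self.entries.items() if len(lst) >= self.max_frequency]
        for c in drop:
            del self.entries[c]

    def get(self, code: int) -> list[tuple[int, int, bool]]:
        return self.entries.get(code, [])


def build_table(
    seqs: Sequence[Read],
    k: int,
    w: int,
    spec: Spectrum15,
    model: RankModel | None = None,
    max_frequency: int | None = None,
) -> MinimizerTable:
    """Insert all minimizers of `seqs`, then purge over-frequent codes."""
    if model is None:
        model = RankModel.from_spectrum(spec)
    table = MinimizerTable(
        k=k,
        w=w,
        seq_names=[s.name for s in seqs],
        seq_lengths=[len(s) for s in seqs],
        max_frequency=max_frequency,
    )
    for idx, s in enumerate(seqs):
        pos, code, h, rev = _minimizer_arrays(s.sequence, k, w, spec, model)
        table.add_sequence(idx, pos, code, rev)
    table.purge_frequent()
    return table


@dataclass
class AlignmentHit:
    """Reference-aligner output (unmapped when contig is None).

    `start` is the predicted reference coordinate of the read's leftmost
    base and may be negative when the read hangs over the reference
    start; 1-based output formats clamp it at write time.
    """

    read_name: str
    contig: str | None
    start: int
    reverse: bool
    score: int
    mapq: int


def align_read(
    table: MinimizerTable,
    read: Read,
    spec: Spectrum15,
    model: RankModel | None = None,
) -> AlignmentHit:
    """Map one read against a reference minimizer table.

    Read minimizer hits are interpreted as ungapped k-mer matches and
    clustered by the reference start they predict for the read; the
    largest cluster wins.  Mapping quality is a 60*(1 - second/first
    cluster size) proxy, capped to [0, 60].
    """
    from olcasm.overlap_graph import cluster_hits_arrays

    if model is None:
        model = RankModel.from_spectrum(spec)
    pos, code, h, rev = _minimizer_arrays(read.sequence, table.k, table.w, spec, model)
    qlen = len(read)
    by_subject: dict[int, list[tuple[int, int, bool]]] = {}
    for p, c, r in zip(pos.tolist(), code.tolist(), rev.tolist()):
        for sid, spos, srev in table.get(c):
            by_subject.setdefault(sid, []).append((p, spos, r != srev))
    best: list[tuple[int, int, float, bool]] = []  # (size, sid, start, reverse)
    for sid, hits in by_subject.items():
        qp = np.array([hh[0] for hh in hits], dtype=np.int64)
        sp = np.array([hh[1] for hh in hits], dtype=np.int64)
        rv = np.array([hh[2] for hh in hits], dtype=bool)
        for reverse in (False, True):
            mask = rv == reverse
            if not mask.any():
                continue
            if reverse:
                starts = sp[mask] - (qlen - qp[mask] - table.k)
            else:
                starts = sp[mask] - qp[mask]
            for members, centroid in cluster_hits_arrays(starts, delta=max(100, qlen // 100)):
                best.append((int(members.size), sid, float(centroid), reverse))
    if not best:
        return AlignmentHit(read.name, None, -1, False, 0, 0)
    best.sort(key=lambda t: (-t[0], t[1], t[2]))
    size, sid, start, reverse = best[0]
    second = best[1][0] if len(best) > 1 else 0
    mapq = int(max(0, min(60, round(60 * (1 - second / size)))))
    return AlignmentHit(
        read.name,
        table.seq_names[sid],
        int(round(start)),
        reverse,
        size,
        mapq,
    )
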