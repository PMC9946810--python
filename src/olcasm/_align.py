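"""Alignment kernels used by consensus construction and polishing.

The dovetail (overlap) kernel scores a read prefix against a contig
suffix with free leading gaps on the contig side and a free read
overhang, which neither a global nor an infix aligner provides directly.
Base-level read-to-contig realignment for polishing goes through edlib
(infix mode with an extended CIGAR).
"""

from __future__ import annotations

import numpy as np
from numba import njit

import edlib

from olcasm.seqio import seq_to_codes

MATCH = 1
MISMATCH = -2
GAP = -2


@njit(cache=True)
def _overlap_kernel(t: np.ndarray, r: np.ndarray, min_j: int) -> tuple[int, int]:
    """Dovetail score DP: t = contig tail codes, r = read prefix codes.

    The alignment may start at any row of t (free leading contig gaps),
    is anchored at read position 0, must consume all of t (reach the
    contig end), and leaves the rest of the read as overhang.  Returns
    (best score, read bases consumed).
    """
    Lt, Lr = len(t), len(r)
    prev = np.empty(Lr + 1, dtype=np.int32)
    cur = np.empty(Lr + 1, dtype=np.int32)
    for j in range(Lr + 1):
        prev[j] = GAP * j
    for i in range(1, Lt + 1):
        cur[0] = 0
        ti = t[i - 1]
        for j in range(1, Lr + 1):
            v = prev[j - 1] + (MATCH if ti == r[j - 1] else MISMATCH)
            a = prev[j] + GAP
            if a > v:
                v = a
            a = cur[j - 1] + GAP
            if a > v:
                v = a
            cur[j] = v
        tmp = prev
        prev = cur
        cur = tmp
    best = -(1 << 30)
    bestj = 0
    jmin = min_j if min_j < Lr else Lr
    for j in range(jmin, Lr + 1):
        if prev[j] > best:
            best = prev[j]
            bestj = j
    return best, bestj


def overlap_align(
    contig_tail: str, read_prefix: str, min_overlap: int = 64
) -> tuple[float, int]:
    """Align a read prefix onto a contig suffix (dovetail).

    Returns (identity, overlap length in read bases).  The score DP picks
    the overlap length; the identity is then the edit-distance identity
    of that read prefix against the contig suffix (end-anchored
    semi-global alignment), which unrelated sequences cannot fake.
    """
    if not contig_tail or not read_prefix:
        return 0.0, 0
    t = seq_to_codes(contig_tail)
    r = seq_to_codes(read_prefix)
    # alignments shorter than min_overlap read bases are uninformative and
    # would let unrelated sequences pass the identity check
    score, bestj = _overlap_kernel(t, r, min_overlap)
    if bestj <= 0:
        return 0.0, 0
    res = edlib.align(read_prefix[:bestj][::-1], contig_tail[::-1], mode="SHW")
    dist = res["editDistance"]
    if dist < 0:
        return 0.0, 0
    return max(0.0, 1.0 - dist / bestj), int(bestj)


# cigar ops consuming (read, ref)
_OP_CONSUMES = {"=": (1, 1), "X": (1, 1), "M": (1, 1), "I": (1, 0), "D": (0, 1)}


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = []
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            ops.append((ch, num))
            num = 0
    return ops


def glocal_align(read_seq: str, window_seq: str) -> tuple[int, int, list[tuple[str, int]]] | None:
    """Align a whole read inside a contig window (free window-end gaps).

    Returns (distance, start offset of the alignment within the window,
    cigar ops) or None when edlib reports no alignment.
    """
    res = edlib.align(read_seq, window_seq, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    start = res["locations"][0][0]
    return res["editDistance"], start, _parse_cigar(res["cigar"])


def edit_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences (edlib NW)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))
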