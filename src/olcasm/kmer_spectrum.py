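"""15-mer spectrum, count-rank model, and the rank-based k-mer hash.

The spectrum is a fixed array of 4**15 = 2**30 saturating counters (cap
2**15 - 1), so memory use is independent of input size.  The count
distribution yields the sequencing-depth mode and an assembly-size
estimate.  Each k-mer (k >= 15) is hashed from the spectrum count x of
its 15-mer suffix:

    h(b) = cumBelow(r(x)) + b mod primeAbove(x),   r(x) = 2*|x - mode|

where cumBelow(r) counts distinct 15-mers with rank strictly below r and
primeAbove(x) is the smallest prime > x.  Single-copy (modal-count)
k-mers therefore get the smallest hashes and the highest priority to be
selected as minimizers; repeat k-mers are deprioritized but never
discarded.  The mod-prime term simulates randomness within a rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from olcasm.seqio import Read, reverse_complement, seq_to_codes

K15 = 15
MASK15 = (1 << 30) - 1
COUNT_CAP = (1 << 15) - 1  # two-byte saturating counters
SPECTRUM_SIZE = 1 << 30


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 2-bit codes of every k-mer of `seq`.

    Returns (codes: uint64[n-k+1], valid: bool[n-k+1]); windows touching
    an N are invalid (their code entry is meaningless and must be masked).
    """
    vals = seq_to_codes(seq)
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    ok = vals != 255
    v = np.where(ok, vals, 0).astype(np.uint64)
    powers = np.power(np.uint64(4), np.arange(k - 1, -1, -1, dtype=np.uint64))
    win = np.lib.stride_tricks.sliding_window_view(v, k)
    codes = (win * powers).sum(axis=1, dtype=np.uint64)
    valid = np.lib.stride_tricks.sliding_window_view(ok, k).all(axis=1)
    return codes, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement codes, vectorized (digit-reverse + complement)."""
    rc = np.zeros_like(codes)
    c = codes.copy()
    three = np.uint64(3)
    two = np.uint64(2)
    for _ in range(k):
        rc = (rc << two) | (three - (c & three))
        c >>= two
    return rc


class SpectrumError(ValueError):
    """No countable 15-mer in the input."""


@dataclass
class Spectrum15:
    """Fixed-size 15-mer count table plus derived statistics.

    With the default both-strand policy every 15-mer instance increments
    its own code and its reverse-complement code, so counts are
    strand-symmetric and the mode reflects total (both-strand) depth.
    """

    counts: np.ndarray  # uint16[2**30]
    total_instances: int
    distinct_codes: np.ndarray  # sorted uint64 codes with count >= 1
    strands: int  # 2 = both-strand counting, 1 = canonical-only
    mode: int = 0
    genome_size_estimate: int = 0
    mode_warning: bool = False
    histogram: dict[int, int] = field(default_factory=dict)

    def lookup(self, codes15: np.ndarray) -> np.ndarray:
        """Counts for an array of 15-mer codes under the counting policy."""
        codes15 = np.asarray(codes15, dtype=np.uint64)
        if self.strands == 1:
            codes15 = np.minimum(codes15, revcomp_codes(codes15, K15))
        return self.counts[codes15].astype(np.int64)

    def count(self, code15: int) -> int:
        return int(self.lookup(np.array([code15], dtype=np.uint64))[0])

    def histogram_array(self) -> np.ndarray:
        """Dense histogram h[c] = number of distinct 15-mers with count c."""
        vals = self.counts[self.distinct_codes]
        return np.bincount(vals, minlength=2)


def build_spectrum(reads: Sequence[Read], canonical: bool = False) -> Spectrum15:
    """Count every N-free 15-mer instance of `reads` into the fixed table.

    Counting is both-strand by default (each instance contributes its
    forward and reverse-complement code); `canonical=True` switches to
    counting min(code, rc-code) once per instance.
    """
    chunks: list[np.ndarray] = []
    for read in reads:
        codes, valid = kmer_codes(read.sequence, K15)
        if codes.size == 0:
            continue
        fwd = codes[valid]
        if fwd.size == 0:
            continue
        rc = revcomp_codes(fwd, K15)
        if canonical:
            chunks.append(np.minimum(fwd, rc))
        else:
            chunks.append(fwd)
            chunks.append(rc)
    if not chunks:
        raise SpectrumError("no countable 15-mer in input reads")
    all_codes = np.concatenate(chunks)
    distinct, occ = np.unique(all_codes, return_counts=True)
    counts = np.zeros(SPECTRUM_SIZE, dtype=np.uint16)
    counts[distinct] = np.minimum(occ, COUNT_CAP).astype(np.uint16)
    spec = Spectrum15(
        counts=counts,
        total_instances=int(all_codes.size),
        distinct_codes=distinct,
        strands=1 if canonical else 2,
    )
    hist = spec.histogram_array()
    spec.histogram = {int(c): int(n) for c, n in enumerate(hist) if c >= 1 and n > 0}
    mode, size, warn = estimate_mode_and_size(spec)
    spec.mode, spec.genome_size_estimate, spec.mode_warning = mode, size, warn
    return spec


def estimate_mode_and_size(spec: Spectrum15) -> tuple[int, int, bool]:
    """Depth mode and assembly-size estimate from the count histogram.

    The error peak at low counts is excluded by scanning the dense
    histogram upward from x=1 for the first valley (first strict rise
    h[x+1] > h[x]); the mode is the argmax beyond it.  A monotonically
    decreasing histogram (no second peak) falls back to mode 1 with a
    warning flag.  The size estimate divides total counted instances by
    the mode, and by the number of counted strands (both-strand counting
    doubles every instance).
    """
    if not spec.histogram:
        raise SpectrumError("empty spectrum histogram")
    hist = spec.histogram_array()
    valley = 0
    for x in range(1, len(hist) - 1):
        if hist[x + 1] > hist[x]:
            valley = x
            break
    counts_axis = np.arange(len(hist), dtype=np.float64)
    if valley == 0:
        mode, warn = 1, True
        depth = 1.0
        good_instances = float(spec.total_instances)
    else:
        mode = int(np.argmax(hist[valley + 1 :]) + valley + 1)
        warn = False
        # discrete argmax is noisy; the size estimate uses the weighted
        # mean count over the peak neighbourhood as the depth instead
        lo, hi = max(1, mode // 2), min(len(hist) - 1, mode + mode // 2)
        c = np.arange(lo, hi + 1, dtype=np.float64)
        mass = hist[lo : hi + 1].astype(np.float64)
        depth = float((c * mass).sum() / mass.sum()) if mass.sum() > 0 else float(mode)
        # instances in the error peak (counts at or below the valley) are
        # sequencing noise, not genome sequence; exclude them from the size
        good_instances = float(
            (counts_axis[valley + 1 :] * hist[valley + 1 :]).sum()
        )
    size = int(round(good_instances / depth / spec.strands))
    return mode, size, warn


def rank(x: int | np.ndarray, mode: int):
    """Rank of a count: twice its distance from the spectrum mode."""
    return 2 * np.abs(np.asarray(x, dtype=np.int64) - mode)


def _sieve_next_prime(limit: int) -> np.ndarray:
    """next_prime[x] = smallest prime > x, for x in [0, limit]."""
    sieve_to = limit + 100
    is_prime = np.ones(sieve_to + 1, dtype=bool)
    is_prime[:2] = False
    for p in range(2, int(sieve_to**0.5) + 1):
        if is_prime[p]:
            is_prime[p * p :: p] = False
    primes = np.flatnonzero(is_prime)
    # for each x, first prime strictly greater than x
    idx = np.searchsorted(primes, np.arange(limit + 1), side="right")
    return primes[idx].astype(np.int64)


@dataclass
class RankModel:
    """Precomputed rank -> cumulative-distinct table and next-prime table."""

    mode: int
    cum_by_rank: np.ndarray  # int64[2*COUNT_CAP + 2]
    next_prime: np.ndarray  # int64[COUNT_CAP + 1]

    @classmethod
    def from_spectrum(cls, spec: Spectrum15) -> "RankModel":
        hist = spec.histogram_array()
        counts = np.arange(len(hist), dtype=np.int64)
        ranks = 2 * np.abs(counts - spec.mode)
        per_rank = np.zeros(2 * COUNT_CAP + 2, dtype=np.int64)
        np.add.at(per_rank, ranks[1:], hist[1:])  # count>=1 only: distinct k-mers
        cum = np.zeros_like(per_rank)
        cum[1:] = np.cumsum(per_rank)[:-1]
        return cls(mode=spec.mode, cum_by_rank=cum, next_prime=_sieve_next_prime(COUNT_CAP))

    def rank_of(self, x) -> np.ndarray:
        return rank(x, self.mode)

    def cum_below(self, r) -> np.ndarray:
        return self.cum_by_rank[np.minimum(np.asarray(r), len(self.cum_by_rank) - 1)]

    def prime_above(self, x) -> np.ndarray:
        return self.next_prime[np.minimum(np.asarray(x, dtype=np.int64), COUNT_CAP)]


def hash_codes(
    codes: np.ndarray, k: int, spec: Spectrum15, model: RankModel
) -> np.ndarray:
    """Vectorized h(b) for an array of k-mer codes (k >= 15).

    x is the spectrum count of the 15-mer suffix of each code.
    """
    if k < K15:
        raise ValueError("hash requires k >= 15 (15-mer suffix undefined)")
    codes = np.asarray(codes, dtype=np.uint64)
    suffix = codes & np.uint64(MASK15)
    x = spec.lookup(suffix)
    r = rank(x, model.mode)
    primes = model.prime_above(x)
    return model.cum_below(r) + (codes % primes.astype(np.uint64)).astype(np.int64)


def hash_kmer(b: int, k: int, spec: Spectrum15, model: RankModel) -> int:
    """Scalar h(b); see :func:`hash_codes`."""
    return int(hash_codes(np.array([b], dtype=np.uint64), k, spec, model)[0])


def correct_read(read: Read, spec: Spectrum15, min_solid: int | None = None) -> Read:
    """Spectrum-based substitution error correction.

    Scans left to right; at each position whose overlapping 15-mers all
    have count below `min_solid`, tries the three substitutions and
    accepts the unique one that lifts every overlapping 15-mer to
    `min_solid` or more.  Unfixable positions (including adjacent double
    substitutions, which single changes cannot repair) are left alone.
    """
    if min_solid is None:
        min_solid = max(3, spec.mode // 4)
    seq = list(read.sequence)
    n = len(seq)
    if n < K15:
        return read

    def window_count(start: int) -> int:
        kmer = seq[start : start + K15]
        if "N" in kmer:
            return min_solid  # N windows are skipped, never flagged weak
        code = 0
        for ch in kmer:
            code = (code << 2) | "ACGT".index(ch)
        return spec.count(code)

    for i in range(n):
        if seq[i] == "N":
            continue
        lo = max(0, i - K15 + 1)
        hi = min(i, n - K15)
        if lo > hi:
            continue
        if any(window_count(s) >= min_solid for s in range(lo, hi + 1)):
            continue
        original = seq[i]
        fixes = []
        for alt in "ACGT":
            if alt == original:
                continue
            seq[i] = alt
            if all(window_count(s) >= min_solid for s in range(lo, hi + 1)):
                fixes.append(alt)
        seq[i] = original
        if len(fixes) == 1:
            seq[i] = fixes[0]
    return Read(read.name, "".join(seq))
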