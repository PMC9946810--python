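"""Assembly and alignment benchmarking.

Nx/N50/NG50 contiguity statistics, alignment accuracy (aligned fraction
and positional RMSE against the truth encoded in simulated read names),
and a windowed parental-specific-k-mer switch-error finder for phased
assemblies (20-kbp windows, 10-kbp step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from olcasm.kmer_spectrum import kmer_codes, revcomp_codes
from olcasm.minimizer_index import AlignmentHit
from olcasm.read_simulator import parse_read_truth
from olcasm.seqio import Read


@dataclass
class AssemblyStats:
    total_length: int
    num_contigs: int
    n50: int
    ng50: int | None
    nx_curve: list[tuple[int, int]]  # (x, Nx) for x = 1..100

    def nx(self, x: int) -> int:
        return self.nx_curve[x - 1][1]


def _nx_value(lengths_desc: np.ndarray, target: float) -> int:
    cum = np.cumsum(lengths_desc)
    idx = np.searchsorted(cum, target)
    if idx >= len(lengths_desc):
        return 0  # cumulative length never reaches the target
    return int(lengths_desc[idx])


def assembly_stats(
    contigs: Sequence, genome_size: int | None = None
) -> AssemblyStats:
    """Nx curve and N50/NG50 of a contig set.

    Nx is the length of the contig at which the cumulative
    sorted-descending length first reaches x% of the total assembly
    length (of `genome_size` for NGx; 0 when never reached).
    """
    lengths = np.sort(
        np.array([len(getattr(c, "sequence", c)) for c in contigs], dtype=np.int64)
    )[::-1]
    if lengths.size == 0:
        raise ValueError("no contigs")
    total = int(lengths.sum())
    curve = [(x, _nx_value(lengths, total * x / 100)) for x in range(1, 101)]
    ng50 = None
    if genome_size is not None:
        ng50 = _nx_value(lengths, genome_size * 0.5)
    return AssemblyStats(
        total_length=total,
        num_contigs=int(lengths.size),
        n50=curve[49][1],
        ng50=ng50,
        nx_curve=curve,
    )


@dataclass
class AccuracyReport:
    total_reads: int
    aligned: int
    aligned_fraction: float
    rmse: float | None  # None when nothing aligned
    within: dict[int, float] = field(default_factory=dict)  # tolerance -> fraction
    skipped_names: int = 0


def alignment_accuracy(
    hits: Iterable[AlignmentHit], tolerances: Sequence[int] = (100,)
) -> AccuracyReport:
    """Aligned fraction and positional RMSE from name-encoded truth.

    The per-read error is |aligned start - true start|; unmapped reads
    count in the denominator of the aligned fraction but not in the RMSE.
    """
    errors: list[float] = []
    total = aligned = skipped = 0
    for h in hits:
        total += 1
        try:
            truth = parse_read_truth(h.read_name)
        except (ValueError, IndexError):
            skipped += 1
            continue
        if h.contig is None:
            continue
        aligned += 1
        errors.append(abs(h.start - truth.start))
    err = np.array(errors, dtype=np.float64)
    rmse = float(np.sqrt(np.mean(err**2))) if err.size else None
    within = {
        tol: (float(np.mean(err <= tol)) if err.size else 0.0) for tol in tolerances
    }
    return AccuracyReport(
        total_reads=total,
        aligned=aligned,
        aligned_fraction=aligned / total if total else 0.0,
        rmse=rmse,
        within=within,
        skipped_names=skipped,
    )


def _canonical_kmer_set(seqs: Iterable[str], k: int) -> np.ndarray:
    chunks = []
    for seq in seqs:
        codes, valid = kmer_codes(seq, k)
        fwd = codes[valid]
        if fwd.size:
            chunks.append(np.minimum(fwd, revcomp_codes(fwd, k)))
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(chunks))


@dataclass
class SwitchErrorReport:
    windows: dict[str, list[tuple[int, int, str]]]  # contig -> (start, end, parent)
    switch_count: int
    identical_parents: bool = False


def count_switch_errors(
    assembly: Sequence,
    parent1: Sequence[Read],
    parent2: Sequence[Read],
    k: int = 21,
    window: int = 20_000,
    step: int = 10_000,
    min_hits: int = 10,
) -> SwitchErrorReport:
    """Windowed parental-k-mer switch-error count on a phased assembly.

    Parental-specific k-mers are the canonical k-mers present in exactly
    one parent.  Each 20-kbp window (10-kbp step) is assigned to the
    parent with more specific-k-mer hits (ambiguous when tied or when
    both counts are below `min_hits`); a switch is a pair of consecutive
    assigned windows of one contig with different parents (ambiguous
    windows are skipped transparently).
    """
    set1 = _canonical_kmer_set((r.sequence for r in parent1), k)
    set2 = _canonical_kmer_set((r.sequence for r in parent2), k)
    spec1 = np.setdiff1d(set1, set2, assume_unique=True)
    spec2 = np.setdiff1d(set2, set1, assume_unique=True)
    identical = spec1.size == 0 and spec2.size == 0
    report = SwitchErrorReport(windows={}, switch_count=0, identical_parents=identical)
    for contig in assembly:
        name = getattr(contig, "name", None) or "contig"
        seq = getattr(contig, "sequence", contig)
        codes, valid = kmer_codes(seq, k)
        canon = np.where(
            valid, np.minimum(codes, revcomp_codes(codes, k)), np.uint64(0)
        )
        in1 = np.isin(canon, spec1) & valid
        in2 = np.isin(canon, spec2) & valid
        rows: list[tuple[int, int, str]] = []
        starts = range(0, max(1, len(seq) - window + step), step)
        for s in starts:
            e = min(len(seq), s + window)
            c1 = int(in1[s : max(s, e - k + 1)].sum())
            c2 = int(in2[s : max(s, e - k + 1)].sum())
            if c1 > c2 and c1 >= min_hits:
                parent = "P1"
            elif c2 > c1 and c2 >= min_hits:
                parent = "P2"
            else:
                parent = "ambiguous"
            rows.append((s, e, parent))
        report.windows[name] = rows
        assigned = [p for _, _, p in rows if p != "ambiguous"]
        report.switch_count += sum(
            1 for a, b in zip(assigned, assigned[1:]) if a != b
        )
    return report
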