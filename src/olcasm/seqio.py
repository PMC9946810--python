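"""Sequence containers, FASTA/FASTQ I/O and 2-bit k-mer encoding.

All coordinates in this package are 0-based, half-open; conversion to
1-based happens only at SAM/VCF-style output boundaries.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

# Encoding: A=0, C=1, G=2, T=3; most significant digit = first base.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: sentinel returned by :func:`encode_kmer` when the k-mer contains N
INVALID_KMER = -1

# byte-value -> 2-bit code lookup, 255 marks N/other
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _BASE_LUT[ord(_b)] = _c
    _BASE_LUT[ord(_b.lower())] = _c


class ParseError(ValueError):
    """Malformed FASTA/FASTQ record (carries the offending line number)."""


@dataclass(frozen=True)
class Read:
    """A named DNA sequence over {A,C,G,T,N}, upper-cased on ingestion."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if seq is not self.sequence:
            object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.name!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """2-bit base codes as uint8; N and other letters map to 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_LUT[raw]


def encode_kmer(s: str, k: int | None = None) -> int:
    """Encode an N-free k-mer as an integer in [0, 4**k).

    Returns :data:`INVALID_KMER` if the k-mer contains a non-ACGT base;
    an N is never silently encoded.
    """
    if k is None:
        k = len(s)
    if len(s) != k:
        raise ValueError(f"expected k-mer of length {k}, got {len(s)}")
    if not 1 <= k <= 31:
        raise ValueError("k must be in 1..31")
    code = 0
    for ch in s.upper():
        b = _BASE_CODE.get(ch)
        if b is None:
            return INVALID_KMER
        code = (code << 2) | b
    return code


def decode_kmer(code: int, k: int) -> str:
    if code < 0 or code >= 1 << (2 * k):
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_CODE_BASE[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Code of the reverse complement of the k-mer with this code."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _detect_format(first_char: str) -> str:
    if first_char == ">":
        return "fasta"
    if first_char == "@":
        return "fastq"
    raise ParseError(f"line 1: cannot detect format from leading {first_char!r}")


def _iter_fasta(lines: Iterator[tuple[int, str]]) -> Iterator[Read]:
    name = None
    chunks: list[str] = []
    start_line = 0
    for lineno, line in lines:
        if line.startswith(">"):
            if name is not None:
                yield Read(name, "".join(chunks))
            name = line[1:].split()[0] if len(line) > 1 else ""
            if not name:
                raise ParseError(f"line {lineno}: empty FASTA header")
            chunks = []
            start_line = lineno
        else:
            if name is None:
                raise ParseError(f"line {lineno}: sequence before first header")
            chunks.append(line)
    if name is not None:
        if not chunks:
            raise ParseError(f"line {start_line}: record {name!r} has no sequence")
        yield Read(name, "".join(chunks))


def _iter_fastq(lines: Iterator[tuple[int, str]]) -> Iterator[Read]:
    while True:
        try:
            lineno, header = next(lines)
        except StopIteration:
            return
        if not header.startswith("@"):
            raise ParseError(f"line {lineno}: FASTQ header must start with '@'")
        name = header[1:].split()[0]
        try:
            _, seq = next(lines)
            plus_no, plus = next(lines)
            _, qual = next(lines)
        except StopIteration:
            raise ParseError(f"line {lineno}: truncated FASTQ record {name!r}") from None
        if not plus.startswith("+"):
            raise ParseError(f"line {plus_no}: expected '+' separator")
        if len(seq) != len(qual):
            raise ParseError(
                f"line {lineno}: record {name!r} seq/qual length mismatch "
                f"({len(seq)} vs {len(qual)})"
            )
        yield Read(name, seq)


def load_sequences(path: str | Path, format: str = "auto") -> list[Read]:
    """Load FASTA/FASTQ (plain or gzip) into a list of :class:`Read`.

    Qualities are discarded and lowercase bases are normalized.  Duplicate
    read names raise, as the assembler keys everything by name.
    """
    with _open_maybe_gzip(path) as fh:
        numbered = (
            (i, line.rstrip("\n").rstrip("\r"))
            for i, line in enumerate(fh, start=1)
            if line.strip()
        )
        try:
            first = next(numbered)
        except StopIteration:
            return []
        if format == "auto":
            format = _detect_format(first[1][0])
        chained = _chain_first(first, numbered)
        if format == "fasta":
            reads = list(_iter_fasta(chained))
        elif format == "fastq":
            reads = list(_iter_fastq(chained))
        else:
            raise ValueError(f"unknown format {format!r}")
    seen: set[str] = set()
    for r in reads:
        if r.name in seen:
            raise ParseError(f"duplicate read name {r.name!r}")
        seen.add(r.name)
    return reads


def _chain_first(first, rest) -> Iterator[tuple[int, str]]:
    yield first
    yield from rest


def write_fasta(reads: Iterable[Read], path: str | Path, width: int = 80) -> None:
    """Write FASTA, wrapping sequence lines at `width` columns."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f">{r.name}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def write_fastq(reads: Iterable[Read], path: str | Path, quality_char: str = "5") -> None:
    """Write FASTQ with a constant quality (default Q20, '5')."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")
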