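"""Long-read simulation with ground truth encoded in read names.

Defaults mirror a HiFi-like library: mean length 20 kbp (SD 5 kbp),
substitution rate 0.5%, indel rate 1%.  Each read name carries
`<template>:<start>-<end>:<strand>:<hap>` so downstream evaluation can
recover the true origin without sidecar files (a sidecar TSV is still
written by the CLI for convenience).  All randomness flows from a single
seeded generator, so outputs are reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from olcasm.seqio import Read, reverse_complement

BASES = np.array(list("ACGT"))
MIN_READ_LEN = 200


@dataclass
class SimulationConfig:
    mean_len: float = 20_000.0
    sd_len: float = 5_000.0
    subst_rate: float = 0.005
    indel_rate: float = 0.01
    depth: float | None = None
    num_reads: int | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        for rate in (self.subst_rate, self.indel_rate):
            if not 0.0 <= rate < 0.5:
                raise ValueError("error rates must be in [0, 0.5)")
        if self.mean_len <= 0:
            raise ValueError("mean_len must be positive")
        if (self.depth is None) == (self.num_reads is None):
            raise ValueError("set exactly one of depth / num_reads")


def simulate_genome(length: int, gc_content: float = 0.5, seed: int = 0) -> Read:
    """Random i.i.d. genome with P(G) + P(C) = gc_content."""
    if length < 1_000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    p_at, p_gc = (1 - gc_content) / 2, gc_content / 2
    seq = rng.choice(BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return Read(f"genome_{seed}", "".join(seq))


@dataclass
class DiploidTemplate:
    hap1: Read
    hap2: Read
    variants: list[tuple[int, str, str]]  # (hap1 position, hap1 allele, hap2 allele)


def build_diploid(
    hap1: Read,
    hap2: Read | None = None,
    snv_rate: float = 0.0,
    seed: int = 0,
) -> DiploidTemplate:
    """Pair two haplotypes, or derive hap2 from hap1 by planting SNVs.

    When hap2 is derived, the planted-variant truth table is recorded;
    when two explicit haplotypes are given the truth is their alignment
    difference and is left empty here (the evaluation module works from
    parental k-mers instead).
    """
    if hap2 is not None:
        return DiploidTemplate(hap1, hap2, [])
    rng = np.random.default_rng(seed)
    seq = list(hap1.sequence)
    variants: list[tuple[int, str, str]] = []
    hits = np.flatnonzero(rng.random(len(seq)) < snv_rate)
    for pos in hits:
        ref = seq[pos]
        if ref == "N":
            continue
        alt = rng.choice([b for b in "ACGT" if b != ref])
        seq[pos] = alt
        variants.append((int(pos), ref, alt))
    return DiploidTemplate(hap1, Read(hap1.name + "_hap2", "".join(seq)), variants)


def _apply_errors(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Plant substitutions and indels (half insertions, half deletions).

    Indel lengths are 1 + Geometric(0.5) failures, i.e. mean 2.
    """
    from olcasm.seqio import seq_to_codes

    n = len(seq)
    codes = seq_to_codes(seq).copy()
    if cfg.subst_rate > 0:
        sub = np.flatnonzero((rng.random(n) < cfg.subst_rate) & (codes != 255))
        if sub.size:
            codes[sub] = (codes[sub] + rng.integers(1, 4, sub.size)) % 4
    keep = np.ones(n, dtype=bool)
    insertions: list[tuple[int, str]] = []
    if cfg.indel_rate > 0:
        hits = np.flatnonzero(rng.random(n) < cfg.indel_rate)
        lengths = rng.geometric(0.5, hits.size)
        is_ins = rng.random(hits.size) < 0.5
        for pos, length, ins in zip(hits.tolist(), lengths.tolist(), is_ins.tolist()):
            if ins:
                insertions.append((pos, "".join(rng.choice(BASES, size=length))))
            else:
                keep[pos : pos + length] = False
    lut = "ACGT" + "N"
    chars = np.array(list(lut))
    base_arr = chars[np.minimum(codes, 4)]
    if not insertions:
        return "".join(base_arr[keep].tolist())
    out: list[str] = []
    prev = 0
    for pos, ins_seq in sorted(insertions):
        out.append("".join(base_arr[prev:pos][keep[prev:pos]].tolist()))
        out.append(ins_seq)
        prev = pos
    out.append("".join(base_arr[prev:][keep[prev:]].tolist()))
    return "".join(out)


def simulate_reads(
    template: Read | DiploidTemplate,
    cfg: SimulationConfig,
) -> list[Read]:
    """Sample reads from a haploid or diploid template.

    Per read: haplotype ~ Bernoulli(0.5) (diploid only), start uniform,
    length ~ Normal(mean, sd) truncated to [200, template end], strand ~
    Bernoulli(0.5); substitutions i.i.d., indels split evenly between
    insertions and deletions with length 1 + Geometric(0.5) - 1.
    """
    rng = np.random.default_rng(cfg.seed)
    if isinstance(template, DiploidTemplate):
        haps = [template.hap1, template.hap2]
    else:
        haps = [template]
    min_len = min(len(h) for h in haps)
    if min_len < cfg.mean_len / 4:
        raise ValueError("template shorter than a quarter of the mean read length")
    if cfg.num_reads is not None:
        n = cfg.num_reads
    else:
        total = sum(len(h) for h in haps)
        n = int(round(cfg.depth * total / cfg.mean_len / len(haps)))
    reads: list[Read] = []
    for i in range(n):
        hap_idx = int(rng.integers(0, len(haps))) if len(haps) > 1 else 0
        hap = haps[hap_idx]
        hlen = len(hap)
        start = int(rng.integers(0, max(1, hlen - MIN_READ_LEN)))
        length = int(round(rng.normal(cfg.mean_len, cfg.sd_len)))
        length = max(MIN_READ_LEN, min(length, hlen - start))
        end = start + length
        frag = hap.sequence[start:end]
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            frag = reverse_complement(frag)
        frag = _apply_errors(frag, cfg, rng)
        name = f"{i}_{hap.name}:{start}-{end}:{strand}:{hap_idx + 1}"
        reads.append(Read(name, frag))
    return reads


@dataclass(frozen=True)
class ReadTruth:
    template: str
    start: int
    end: int
    strand: str
    hap: int


def parse_read_truth(name: str) -> ReadTruth:
    """Recover the simulated origin from a read name."""
    body, span, strand, hap = name.rsplit(":", 3)
    template = body.split("_", 1)[1] if "_" in body else body
    start_s, end_s = span.rsplit("-", 1)
    return ReadTruth(template, int(start_s), int(end_s), strand, int(hap))


def truth_table(reads: Sequence[Read]) -> list[tuple[str, ReadTruth]]:
    return [(r.name, parse_read_truth(r.name)) for r in reads]
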