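"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from olcasm.kmer_spectrum import COUNT_CAP, SPECTRUM_SIZE, Spectrum15, build_spectrum
from olcasm.read_simulator import SimulationConfig, simulate_genome, simulate_reads
from olcasm.seqio import Read


def make_spectrum_from_histogram(
    histogram: dict[int, int], mode: int | None = None, codes: dict[int, int] | None = None
) -> Spectrum15:
    """Fabricate a Spectrum15 with a prescribed count histogram.

    `codes` optionally pins specific 15-mer codes to specific counts
    (they must be consistent with the histogram).
    """
    counts = np.zeros(SPECTRUM_SIZE, dtype=np.uint16)
    next_code = 0
    pinned = dict(codes or {})
    remaining = {c: n for c, n in histogram.items()}
    for code, cnt in pinned.items():
        counts[code] = min(cnt, COUNT_CAP)
        remaining[cnt] -= 1
        next_code = max(next_code, code + 1)
    for cnt, n in remaining.items():
        for _ in range(n):
            while counts[next_code] != 0:
                next_code += 1
            counts[next_code] = min(cnt, COUNT_CAP)
            next_code += 1
    distinct = np.flatnonzero(counts[: next_code + 1]).astype(np.uint64)
    total = int(sum(c * n for c, n in histogram.items()))
    spec = Spectrum15(
        counts=counts,
        total_instances=total,
        distinct_codes=distinct,
        strands=2,
        histogram=dict(histogram),
    )
    if mode is not None:
        spec.mode = mode
    return spec


@pytest.fixture(scope="session")
def small_genome() -> Read:
    return simulate_genome(20_000, 0.5, seed=101)


@pytest.fixture(scope="session")
def clean_reads(small_genome) -> list[Read]:
    cfg = SimulationConfig(
        mean_len=2_000, sd_len=500, subst_rate=0.0, indel_rate=0.0, depth=30, seed=102
    )
    return simulate_reads(small_genome, cfg)


@pytest.fixture(scope="session")
def clean_spectrum(clean_reads) -> Spectrum15:
    return build_spectrum(clean_reads)
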