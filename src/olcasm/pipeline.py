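"""End-to-end haploid assembly: spectrum -> graph -> layout -> consensus
-> polish.  The diploid pipeline in :mod:`olcasm.diploid_phasing` reuses
this and re-runs layout after removing cross-haplotype edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from olcasm.consensus import (
    AlignmentRecord,
    Contig,
    Placement,
    circularize,
    consensus_from_layout,
    merge_overlapping_contigs,
    polish,
    realign,
    rescue_unplaced,
)
from olcasm.kmer_spectrum import RankModel, Spectrum15, build_spectrum
from olcasm.layout import Layout, build_layout, fit_distributions, select_safe_edges
from olcasm.overlap_graph import AssemblyGraph, build_graph
from olcasm.seqio import Read

logger = logging.getLogger("olcasm")


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    graph: AssemblyGraph
    layout: Layout
    placements: list[Placement]
    alignments: list[AlignmentRecord]
    spectrum: Spectrum15
    safe_edges: set[int] = field(default_factory=set)


def assemble(
    reads: list[Read],
    k: int = 25,
    w: int = 40,
    origins: list[Read] | None = None,
    polish_rounds: int = 2,
) -> AssemblyResult:
    """Assemble a read set into polished contigs."""
    spec = build_spectrum(reads)
    logger.info(
        "spectrum: mode=%d size_estimate=%d%s",
        spec.mode, spec.genome_size_estimate,
        " (mode fallback)" if spec.mode_warning else "",
    )
    graph = build_graph(reads, k=k, w=w, spec=spec)
    logger.info(
        "graph: %d reads, %d embedded, %d edges",
        len(reads), len(graph.embedded), len(graph.edges),
    )
    safe = select_safe_edges(graph)
    model = fit_distributions([graph.edges[i] for i in safe])
    layout = build_layout(graph, safe, model)
    logger.info(
        "layout: %d paths (%d non-singleton), %d safe edges%s",
        len(layout.paths), len(layout.nonsingleton_paths), len(safe),
        " (fallback edge ranking)" if model.fallback else "",
    )
    contigs, placements = consensus_from_layout(graph, layout)
    contigs, placements = rescue_unplaced(contigs, placements, graph.reads, k=k, w=w)
    contigs, placements = merge_overlapping_contigs(contigs, placements, graph.reads, k=k, w=w)
    alignments = realign(contigs, placements, graph.reads)
    for _ in range(polish_rounds):
        contigs = polish(contigs, alignments, graph.reads)
        alignments = realign(contigs, placements, graph.reads)
    if origins:
        contigs = circularize(contigs, origins)
        alignments = realign(contigs, placements, graph.reads)
    return AssemblyResult(
        contigs=contigs,
        graph=graph,
        layout=layout,
        placements=placements,
        alignments=alignments,
        spectrum=spec,
        safe_edges=safe,
    )
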