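"""Overlap detection from shared minimizers and the undirected
two-vertex-per-read assembly graph.

Each read X contributes vertices X^s (5'-end) and X^e (3'-end).  An
overlap between the end of A and the start of B is the edge {A^e, B^s};
an overlap with the reverse complement of B is {A^e, B^e}.  The graph is
undirected and simple: reads come from either strand of the template
with equal probability, so no a-priori orientation exists.

Edge statistics (overlap, CSK, proportion of evidence) come from a
simulated alignment: minimizer hits are clustered by the subject start
they predict for the query, and cluster geometry replaces a full
pairwise alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from olcasm.kmer_spectrum import RankModel, Spectrum15, build_spectrum
from olcasm.minimizer_index import DEFAULT_K, DEFAULT_W, _minimizer_arrays
from olcasm.seqio import Read

#: a vertex is (read name, end), end in {"s", "e"}
Vertex = tuple[str, str]

CONFIGS = ("SS", "SE", "ES", "EE")


@dataclass(frozen=True)
class KmerHit:
    query_pos: int
    subject_pos: int
    reverse: bool
    predicted_subject_start: int


def make_hit(query_pos: int, subject_pos: int, reverse: bool, query_len: int, k: int) -> KmerHit:
    """Build a hit with its inferred subject start for the (rc-)query."""
    if reverse:
        start = subject_pos - (query_len - query_pos - k)
    else:
        start = subject_pos - query_pos
    return KmerHit(query_pos, subject_pos, reverse, start)


@dataclass
class HitCluster:
    hits: list[KmerHit]
    reverse: bool
    centroid: float
    predicted_overlap: float = 0.0
    csk: int = 0
    num_shared_kmers: int = 0
    first_subj: int = 0
    last_subj: int = 0
    first_query: int = 0
    last_query: int = 0
    prop_evidence: float = 1.0
    config: str | None = None
    embedded: bool = False
    rel_start: int = 0


def cluster_hits_arrays(
    starts: np.ndarray, delta: float, max_rounds: int = 10
) -> list[tuple[np.ndarray, float]]:
    """Group predicted-start values; returns (index array, centroid) pairs.

    Seeds clusters by gaps larger than `delta` in the sorted values, then
    refines assignments to the nearest centroid for up to `max_rounds`
    k-means-style iterations; values further than `delta` from their
    final centroid are dropped as inconsistent evidence.
    """
    starts = np.asarray(starts, dtype=np.float64)
    n = starts.size
    if n == 0:
        return []
    order = np.argsort(starts, kind="stable")
    svals = starts[order]
    breaks = np.flatnonzero(np.diff(svals) > delta) + 1
    groups = np.split(np.arange(n), breaks)
    centroids = np.array([svals[g].mean() for g in groups])
    assign = np.zeros(n, dtype=np.int64)
    for g_idx, g in enumerate(groups):
        assign[g] = g_idx
    for _ in range(max_rounds):
        new_assign = np.abs(svals[:, None] - centroids[None, :]).argmin(axis=1)
        if (new_assign == assign).all():
            break
        assign = new_assign
        centroids = np.array(
            [svals[assign == i].mean() if (assign == i).any() else c
             for i, c in enumerate(centroids)]
        )
    out = []
    for i, c in enumerate(centroids):
        members = np.flatnonzero((assign == i) & (np.abs(svals - c) <= delta))
        if members.size:
            out.append((order[members], float(svals[members].mean())))
    return out


def _cluster_stats(
    hits: list[KmerHit], reverse: bool, centroid: float,
    query_len: int, subject_len: int, k: int,
) -> HitCluster:
    spos = np.array(sorted(h.subject_pos for h in hits), dtype=np.int64)
    qpos = np.array([h.query_pos for h in hits], dtype=np.int64)
    starts = np.array([h.predicted_subject_start for h in hits], dtype=np.float64)
    # per-hit overlap inference in the sign regime of the centroid
    if centroid >= 0:
        overlaps = subject_len - starts
    else:
        overlaps = query_len + starts
    predicted = float(max(1.0, overlaps.mean()))
    predicted = min(predicted, float(min(query_len, subject_len)))
    gaps = np.diff(spos)
    csk = int(k + np.minimum(gaps, k).sum()) if spos.size > 1 else k
    first_subj, last_subj = int(spos[0]), int(spos[-1])
    prop = (last_subj - first_subj + k) / predicted
    prop = float(min(1.0, max(1e-6, prop)))
    return HitCluster(
        hits=hits,
        reverse=reverse,
        centroid=centroid,
        predicted_overlap=predicted,
        csk=min(csk, int(predicted) + k, subject_len),
        num_shared_kmers=len(hits),
        first_subj=first_subj,
        last_subj=last_subj,
        first_query=int(qpos.min()),
        last_query=int(qpos.max()),
        prop_evidence=prop,
    )


def classify_configuration(
    cluster: HitCluster, query_len: int, subject_len: int, k: int = DEFAULT_K
) -> tuple[str, tuple[str, str] | None]:
    """Configuration of a cluster and the vertex ends the edge would join.

    Returns (config, (subject end, query end)) with config one of
    SS/SE/ES/EE (subject letter first), or ("embedded", None) when the
    geometry implies the query is contained in the subject (with 2k bp
    slack at both ends).  Sets cluster.config / cluster.embedded.
    """
    c = cluster.centroid
    tol = 2 * k
    if c >= -tol and c + query_len <= subject_len + tol:
        cluster.embedded = True
        cluster.rel_start = int(max(0, round(c)))
        cluster.config = "embedded"
        cluster.predicted_overlap = float(query_len)
        return "embedded", None
    if not cluster.reverse:
        ends = ("e", "s") if c >= 0 else ("s", "e")
    else:
        ends = ("e", "e") if c >= 0 else ("s", "s")
    config = ends[0].upper() + ends[1].upper()
    cluster.config = config
    return config, ends


def cluster_hits(
    hits: Sequence[KmerHit],
    query_len: int,
    subject_len: int,
    expected_clusters: int = 1,
    k: int = DEFAULT_K,
    delta: float | None = None,
    min_kmers: int = 1,
    min_overlap: float = 0.0,
) -> list[HitCluster]:
    """Cluster hits of one query/subject pair into candidate overlaps.

    Forward and reverse hits are clustered independently on their
    predicted subject starts (within-cluster tolerance delta, default
    max(100 bp, 1% of query length)).  Clusters are sorted by shared
    k-mer count; up to the two largest are retained, and a second one
    only if it supports a different alignment configuration.
    """
    if delta is None:
        delta = max(100.0, 0.01 * query_len)
    clusters: list[HitCluster] = []
    for reverse in (False, True):
        sub = [h for h in hits if h.reverse == reverse]
        if not sub:
            continue
        starts = np.array([h.predicted_subject_start for h in sub], dtype=np.float64)
        for members, centroid in cluster_hits_arrays(starts, delta):
            members_hits = [sub[i] for i in members]
            cl = _cluster_stats(members_hits, reverse, centroid, query_len, subject_len, k)
            classify_configuration(cl, query_len, subject_len, k)
            clusters.append(cl)
    clusters = [
        c for c in clusters
        if c.num_shared_kmers >= min_kmers
        and (c.embedded or c.predicted_overlap >= min_overlap)
    ]
    clusters.sort(key=lambda c: (-c.num_shared_kmers, c.centroid))
    if len(clusters) <= 1:
        return clusters
    retained = [clusters[0]]
    for c in clusters[1:]:
        if c.config != retained[0].config:
            retained.append(c)
            break
    return retained


@dataclass
class Edge:
    u: Vertex
    v: Vertex
    overlap: float
    csk: int
    prop_evidence: float
    num_shared_kmers: int
    log_likelihood: float | None = None
    safe: bool = False

    def key(self) -> tuple[Vertex, Vertex]:
        return (self.u, self.v) if self.u <= self.v else (self.v, self.u)

    def other(self, vertex: Vertex) -> Vertex:
        return self.v if vertex == self.u else self.u


@dataclass
class AssemblyGraph:
    reads: dict[str, Read]
    edges: list[Edge] = field(default_factory=list)
    embedded: list[tuple[str, str, int, bool]] = field(default_factory=list)
    k: int = DEFAULT_K
    w: int = DEFAULT_W
    adjacency: dict[Vertex, list[int]] = field(default_factory=dict)
    degree_mean: float = 0.0
    degree_sd: float = 0.0

    @property
    def embedded_names(self) -> set[str]:
        return {name for name, *_ in self.embedded}

    @property
    def vertices(self) -> list[Vertex]:
        emb = self.embedded_names
        out: list[Vertex] = []
        for name in self.reads:
            if name not in emb:
                out.append((name, "s"))
                out.append((name, "e"))
        return out

    def degree(self, vertex: Vertex) -> int:
        return len(self.adjacency.get(vertex, ()))

    def edges_at(self, vertex: Vertex) -> list[Edge]:
        return [self.edges[i] for i in self.adjacency.get(vertex, ())]

    def finalize(self) -> None:
        """Rebuild adjacency and cache vertex-degree statistics."""
        self.adjacency = {v: [] for v in self.vertices}
        for i, e in enumerate(self.edges):
            self.adjacency[e.u].append(i)
            self.adjacency[e.v].append(i)
        degs = np.array([len(v) for v in self.adjacency.values()], dtype=np.float64)
        self.degree_mean = float(degs.mean()) if degs.size else 0.0
        self.degree_sd = float(degs.std()) if degs.size else 0.0


def build_graph(
    reads: Sequence[Read],
    k: int = DEFAULT_K,
    w: int = DEFAULT_W,
    spec: Spectrum15 | None = None,
    model: RankModel | None = None,
    min_kmers: int = 5,
) -> AssemblyGraph:
    """Build the overlap graph of a read set.

    Reads are processed longest first; each read is queried as a query
    against the minimizer table of the longer (subject) reads, so every
    candidate pair is examined exactly once.  Clusters of consistent
    minimizer hits become edges (or containment records); one edge is
    kept per unordered vertex pair, the one with more shared k-mers.
    Reads found embedded in a longer read get no vertices and do not
    enter the table.
    """
    names = [r.name for r in reads]
    if len(set(names)) != len(names):
        raise ValueError("duplicate read names")
    graph = AssemblyGraph(reads={r.name: r for r in reads}, k=k, w=w)
    if len(reads) < 2:
        graph.finalize()
        return graph
    if spec is None:
        spec = build_spectrum(reads)
    if model is None:
        model = RankModel.from_spectrum(spec)
    order = sorted(reads, key=lambda r: (-len(r), r.name))
    min_overlap = float(w + k - 1)
    table: dict[int, list[tuple[int, int, bool]]] = {}
    by_pair: dict[tuple[Vertex, Vertex], Edge] = {}
    for ridx, read in enumerate(order):
        pos, code, h, rev = _minimizer_arrays(read.sequence, k, w, spec, model)
        qlen = len(read)
        by_subject: dict[int, list[KmerHit]] = {}
        matched_codes: dict[int, set[int]] = {}
        for p, c, r in zip(pos.tolist(), code.tolist(), rev.tolist()):
            entries = table.get(c)
            if not entries:
                continue
            for sid, spn, srev in entries:
                by_subject.setdefault(sid, []).append(
                    make_hit(p, spn, r != srev, qlen, k)
                )
                matched_codes.setdefault(sid, set()).add(c)
        best_embed: tuple[int, int, int, bool] | None = None  # (nk, sid, rel, rev)
        candidate_edges: list[Edge] = []
        for sid, hits in by_subject.items():
            subject = order[sid]
            nk_distinct = len(matched_codes[sid])
            expected = max(1, round(len(hits) / nk_distinct))
            clusters = cluster_hits(
                hits, qlen, len(subject),
                expected_clusters=expected, k=k,
                min_kmers=min_kmers, min_overlap=min_overlap,
            )
            for cl in clusters:
                if cl.embedded:
                    cand = (cl.num_shared_kmers, sid, cl.rel_start, cl.reverse)
                    if best_embed is None or cand[0] > best_embed[0]:
                        best_embed = cand
                    continue
                _, ends = classify_configuration(cl, qlen, len(subject), k)
                if ends is None:
                    continue
                send, qend = ends
                edge = Edge(
                    u=(subject.name, send),
                    v=(read.name, qend),
                    overlap=cl.predicted_overlap,
                    csk=cl.csk,
                    prop_evidence=cl.prop_evidence,
                    num_shared_kmers=cl.num_shared_kmers,
                )
                candidate_edges.append(edge)
        if best_embed is not None:
            nk, sid, rel, is_rev = best_embed
            graph.embedded.append((read.name, order[sid].name, rel, is_rev))
            continue  # no vertices, no table entries, no edges
        for edge in candidate_edges:
            key = edge.key()
            old = by_pair.get(key)
            if old is None or edge.num_shared_kmers > old.num_shared_kmers:
                by_pair[key] = edge
        table_entries = table
        for p, c, r in zip(pos.tolist(), code.tolist(), rev.tolist()):
            table_entries.setdefault(c, []).append((ridx, p, r))
    # drop edges that touch reads later found embedded
    emb = graph.embedded_names
    graph.edges = [
        e for e in by_pair.values() if e.u[0] not in emb and e.v[0] not in emb
    ]
    graph.edges.sort(key=lambda e: e.key())
    graph.finalize()
    return graph


def dump_edges(graph: AssemblyGraph, path) -> None:
    """Diagnostic TSV edge list (non-standard format, debugging only)."""
    with open(path, "w") as fh:
        fh.write("readA\tendA\treadB\tendB\toverlap\tcsk\tnSharedKmers\tpropEvidence\n")
        for e in graph.edges:
            fh.write(
                f"{e.u[0]}\t{e.u[1]}\t{e.v[0]}\t{e.v[1]}\t"
                f"{e.overlap:.1f}\t{e.csk}\t{e.num_shared_kmers}\t{e.prop_evidence:.4f}\n"
            )
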