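"""Layout construction as an edge-selection problem.

Edges that are reciprocal best for both of their vertices in overlap
length AND in CSK, and whose vertices have a total degree below
mean + 3 SD, are "safe" and seed the layout paths.  Normal distributions
are fitted to overlap and CSK of the safe edges and a beta distribution
to the proportion of evidence; every remaining edge is scored by the sum
of log lower-tail P-values of its three features and edges are selected
greedily in descending score, subject to the matching condition (no
vertex in two selected edges) and acyclicity over reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from olcasm.overlap_graph import AssemblyGraph, Edge, Vertex

LOG_FLOOR = math.log(1e-300)


def select_safe_edges(graph: AssemblyGraph) -> set[int]:
    """Indices of safe edges of the graph.

    An edge is safe iff it attains the maximum overlap AND the maximum
    CSK among the edges of each of its two vertices, and both vertices
    have degree < mean + 3 SD of the vertex-degree distribution.
    """
    cutoff = graph.degree_mean + 3 * graph.degree_sd
    best_overlap: dict[Vertex, float] = {}
    best_csk: dict[Vertex, int] = {}
    for v, idxs in graph.adjacency.items():
        if idxs:
            best_overlap[v] = max(graph.edges[i].overlap for i in idxs)
            best_csk[v] = max(graph.edges[i].csk for i in idxs)
    safe: set[int] = set()
    for i, e in enumerate(graph.edges):
        if graph.degree(e.u) >= cutoff or graph.degree(e.v) >= cutoff:
            continue
        if (
            e.overlap >= best_overlap[e.u]
            and e.overlap >= best_overlap[e.v]
            and e.csk >= best_csk[e.u]
            and e.csk >= best_csk[e.v]
        ):
            safe.add(i)
            e.safe = True
    return safe


@dataclass
class EdgeFeatureModel:
    """Feature distributions fitted from safe edges only.

    overlap, csk ~ Normal (sample mean/SD, SD floored at 1.0);
    prop_evidence ~ Beta (method of moments).  `fallback` is set when
    fewer than 10 safe edges were available; edges are then ranked
    lexicographically by (overlap, csk) instead of by likelihood.
    """

    overlap_mu: float = 0.0
    overlap_sigma: float = 1.0
    csk_mu: float = 0.0
    csk_sigma: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    fallback: bool = False


def _beta_moments(values: np.ndarray) -> tuple[float, float]:
    v = np.clip(values, 1e-6, 1 - 1e-6)
    m = float(v.mean())
    var = float(v.var())
    if var < 1e-9:
        var = 1e-9
    common = m * (1 - m) / var - 1
    if common <= 0:
        common = 1e-3
    return max(1e-3, m * common), max(1e-3, (1 - m) * common)


def fit_distributions(safe_edges: list[Edge]) -> EdgeFeatureModel:
    if len(safe_edges) < 10:
        return EdgeFeatureModel(fallback=True)
    ov = np.array([e.overlap for e in safe_edges], dtype=np.float64)
    csk = np.array([e.csk for e in safe_edges], dtype=np.float64)
    prop = np.array([e.prop_evidence for e in safe_edges], dtype=np.float64)
    a, b = _beta_moments(prop)
    return EdgeFeatureModel(
        overlap_mu=float(ov.mean()),
        overlap_sigma=max(1.0, float(ov.std())),
        csk_mu=float(csk.mean()),
        csk_sigma=max(1.0, float(csk.std())),
        alpha=a,
        beta=b,
    )


def edge_log_likelihood(edge: Edge, model: EdgeFeatureModel) -> float:
    """Summed log lower-tail CDFs of the edge features.

    The lower tail makes larger overlap/CSK/evidence more credible, so
    strong edges rank first; each term is floored at log(1e-300).
    """
    p_ov = stats.norm.cdf(edge.overlap, model.overlap_mu, model.overlap_sigma)
    p_csk = stats.norm.cdf(edge.csk, model.csk_mu, model.csk_sigma)
    p_prop = stats.beta.cdf(
        min(1 - 1e-9, max(1e-9, edge.prop_evidence)), model.alpha, model.beta
    )
    total = 0.0
    for p in (p_ov, p_csk, p_prop):
        total += math.log(p) if p > 1e-300 else LOG_FLOOR
    edge.log_likelihood = total
    return total


@dataclass
class Layout:
    """Ordered, oriented read paths plus the selected edge per junction."""

    paths: list[list[tuple[str, bool]]] = field(default_factory=list)
    path_edges: list[list[Edge]] = field(default_factory=list)

    @property
    def nonsingleton_paths(self) -> list[list[tuple[str, bool]]]:
        return [p for p in self.paths if len(p) > 1]


class _DisjointSet:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        parent = self.parent
        root = parent.setdefault(x, x)
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        self.parent[self.find(a)] = self.find(b)


def _edge_sort_key(e: Edge) -> tuple:
    score = e.log_likelihood if e.log_likelihood is not None else 0.0
    return (-score, -e.overlap, -e.csk, e.key())


def build_layout(
    graph: AssemblyGraph,
    safe: set[int] | None = None,
    model: EdgeFeatureModel | None = None,
) -> Layout:
    """Greedy layout: safe edges first, then score-descending augmentation.

    An edge is selected iff neither endpoint vertex already carries a
    selected edge and the edge does not connect two reads already on the
    same path (cycle test through a disjoint set over reads, with each
    read's two vertices pre-united).  Every non-embedded read ends up in
    exactly one path, possibly a singleton.
    """
    if safe is None:
        safe = select_safe_edges(graph)
    safe_edges = [graph.edges[i] for i in safe]
    if model is None:
        model = fit_distributions(safe_edges)
    rest = [e for i, e in enumerate(graph.edges) if i not in safe]
    if model.fallback:
        rest.sort(key=lambda e: (-e.overlap, -e.csk, e.key()))
    else:
        for e in rest:
            edge_log_likelihood(e, model)
        rest.sort(key=_edge_sort_key)
    safe_edges.sort(key=lambda e: (-e.overlap, -e.csk, e.key()))

    dsu = _DisjointSet()
    used: dict[Vertex, Edge] = {}
    selected: list[Edge] = []
    for e in safe_edges + rest:
        if e.u in used or e.v in used:
            continue
        if dsu.find(e.u[0]) == dsu.find(e.v[0]):
            continue  # would close a cycle within one path
        used[e.u] = e
        used[e.v] = e
        dsu.union(e.u[0], e.v[0])
        selected.append(e)

    return _extract_paths(graph, used)


def _extract_paths(graph: AssemblyGraph, used: dict[Vertex, Edge]) -> Layout:
    emb = graph.embedded_names
    read_names = [n for n in graph.reads if n not in emb]
    layout = Layout()
    visited: set[str] = set()
    for name in sorted(read_names):
        if name in visited:
            continue
        # find a free port to start from; a full cycle cannot occur
        # (selection forbids closing one), so every path has an end
        if (name, "s") not in used:
            start_end = "s"
        elif (name, "e") not in used:
            start_end = "e"
        else:
            continue  # interior read; reached from a terminal read later
        path: list[tuple[str, bool]] = []
        edges: list[Edge] = []
        cur, enter = name, start_end
        while True:
            forward = enter == "s"
            path.append((cur, not forward))
            visited.add(cur)
            exit_vertex = (cur, "e" if forward else "s")
            edge = used.get(exit_vertex)
            if edge is None:
                break
            edges.append(edge)
            nxt, nxt_end = edge.other(exit_vertex)
            cur, enter = nxt, nxt_end
        if path[-1][0] < path[0][0]:
            path.reverse()
            edges.reverse()
            path = [(n, not r) for n, r in path]
        layout.paths.append(path)
        layout.path_edges.append(edges)
    # interior reads never reached would indicate a cycle; selection forbids it
    remaining = set(read_names) - visited
    assert not remaining, f"cyclic layout component: {sorted(remaining)[:3]}"
    layout.paths, layout.path_edges = _sort_paths(layout)
    return layout


def _sort_paths(layout: Layout) -> tuple[list, list]:
    order = sorted(range(len(layout.paths)), key=lambda i: layout.paths[i][0][0])
    return [layout.paths[i] for i in order], [layout.path_edges[i] for i in order]
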