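import itertools
import math

import numpy as np
import pytest

from olcasm.layout import (
    EdgeFeatureModel,
    build_layout,
    edge_log_likelihood,
    fit_distributions,
    select_safe_edges,
)
from olcasm.overlap_graph import AssemblyGraph, Edge
from olcasm.pipeline import assemble
from olcasm.read_simulator import (
    SimulationConfig,
    parse_read_truth,
    simulate_genome,
    simulate_reads,
)
from olcasm.seqio import Read


def make_graph(read_names, edge_specs):
    """Graph from (u, uend, v, vend, overlap, csk, prop, nk) tuples."""
    reads = {n: Read(n, "ACGT" * 300) for n in read_names}
    g = AssemblyGraph(reads=reads)
    for u, ue, v, ve, ov, csk, prop, nk in edge_specs:
        g.edges.append(Edge((u, ue), (v, ve), ov, csk, prop, nk))
    g.finalize()
    return g


class TestSafeEdges:
    def test_reciprocal_best_single_edge(self):
        g = make_graph(
            "ABCD",
            [
                ("A", "e", "B", "s", 1000, 800, 0.9, 40),
                ("C", "e", "D", "s", 900, 700, 0.9, 35),
            ],
        )
        assert select_safe_edges(g) == {0, 1}

    def test_best_overlap_and_csk_must_agree(self):
        # u's best-overlap edge is not its best-csk edge: neither is safe for u
        g = make_graph(
            "ABC",
            [
                ("A", "e", "B", "s", 1000, 500, 0.9, 40),  # best overlap at A^e
                ("A", "e", "C", "s", 800, 900, 0.9, 35),   # best csk at A^e
            ],
        )
        assert select_safe_edges(g) == set()

    def test_degree_outlier_hub_excluded(self):
        # hub vertex with degree far above the rest: its edges are unsafe
        hub_edges = [
            ("H", "e", f"R{i}", "s", 1000 - i, 800 - i, 0.9, 40) for i in range(12)
        ]
        chain = [(f"R{i}", "e", f"R{i+1}", "s", 500, 400, 0.8, 20) for i in range(4)]
        g = make_graph(["H"] + [f"R{i}" for i in range(12)], hub_edges + chain)
        cutoff = g.degree_mean + 3 * g.degree_sd
        assert g.degree(("H", "e")) >= cutoff
        safe = select_safe_edges(g)
        assert all(g.edges[i].u[0] != "H" and g.edges[i].v[0] != "H" for i in safe)


class TestFitDistributions:
    def test_fallback_below_ten_edges(self):
        model = fit_distributions(
            [Edge(("A", "e"), ("B", "s"), 100, 80, 0.9, 10)] * 5
        )
        assert model.fallback

    def test_degenerate_variance_floored(self):
        edges = [
            Edge((f"r{i}", "e"), (f"q{i}", "s"), 10_000, 9_000, 0.9, 50)
            for i in range(50)
        ]
        model = fit_distributions(edges)
        assert model.overlap_mu == pytest.approx(10_000)
        assert model.overlap_sigma == 1.0

    def test_beta_moments_solution(self):
        rng = np.random.default_rng(71)
        # target mean 0.9, variance 0.0081
        m, v = 0.9, 0.0081
        common = m * (1 - m) / v - 1
        a_true, b_true = m * common, (1 - m) * common
        props = rng.beta(a_true, b_true, size=5_000)
        edges = [
            Edge((f"r{i}", "e"), (f"q{i}", "s"), 1_000, 800, float(p), 30)
            for i, p in enumerate(props)
        ]
        model = fit_distributions(edges)
        assert model.alpha / (model.alpha + model.beta) == pytest.approx(
            props.mean(), rel=1e-6
        )
        assert model.alpha == pytest.approx(a_true, rel=0.2)

    def test_normal_fit_recovers_parameters(self):
        rng = np.random.default_rng(72)
        ov = rng.normal(5_000, 500, size=10_000)
        edges = [
            Edge((f"r{i}", "e"), (f"q{i}", "s"), float(o), float(o) * 0.8, 0.9, 30)
            for i, o in enumerate(ov)
        ]
        model = fit_distributions(edges)
        assert model.overlap_mu == pytest.approx(5_000, rel=0.01)
        assert model.overlap_sigma == pytest.approx(500, rel=0.05)


class TestEdgeLogLikelihood:
    def model(self):
        return EdgeFeatureModel(
            overlap_mu=1_000, overlap_sigma=100, csk_mu=800, csk_sigma=80,
            alpha=2.0, beta=2.0,
        )

    def test_all_median_features_score_3_log_half(self):
        m = self.model()
        e = Edge(("A", "e"), ("B", "s"), 1_000, 800, 0.5, 30)
        assert edge_log_likelihood(e, m) == pytest.approx(3 * math.log(0.5))

    def test_monotone_in_each_feature(self):
        m = self.model()
        base = edge_log_likelihood(Edge(("A", "e"), ("B", "s"), 1_000, 800, 0.5, 30), m)
        assert edge_log_likelihood(Edge(("A", "e"), ("B", "s"), 1_100, 800, 0.5, 30), m) > base
        assert edge_log_likelihood(Edge(("A", "e"), ("B", "s"), 1_000, 900, 0.5, 30), m) > base
        assert edge_log_likelihood(Edge(("A", "e"), ("B", "s"), 1_000, 800, 0.7, 30), m) > base

    def test_dominance(self):
        m = self.model()
        hi = edge_log_likelihood(Edge(("A", "e"), ("B", "s"), 1_200, 900, 0.8, 30), m)
        lo = edge_log_likelihood(Edge(("C", "e"), ("D", "s"), 900, 700, 0.4, 30), m)
        assert hi > lo

    def test_floor_guards_against_minus_inf(self):
        m = self.model()
        s = edge_log_likelihood(Edge(("A", "e"), ("B", "s"), -1e9, -1e9, 1e-12, 1), m)
        assert math.isfinite(s)


def brute_force_best_matching(graph):
    """Exhaustive max-total-shifted-score acyclic vertex matching.

    Scores are log-probabilities (negative); the greedy selector adds
    every admissible edge, so the reference objective rewards
    cardinality first via a constant shift larger than any score range.
    """
    SHIFT = 10_000.0
    edges = graph.edges
    best_set, best_score = frozenset(), -1.0
    for r in range(len(edges) + 1):
        for comb in itertools.combinations(range(len(edges)), r):
            used = set()
            parent = {}

            def find(x):
                while parent.setdefault(x, x) != x:
                    x = parent[x]
                return x

            ok = True
            total = 0.0
            for i in comb:
                e = edges[i]
                if e.u in used or e.v in used:
                    ok = False
                    break
                ra, rb = find(e.u[0]), find(e.v[0])
                if ra == rb:
                    ok = False
                    break
                parent[ra] = rb
                used.add(e.u)
                used.add(e.v)
                total += SHIFT + e.log_likelihood
            if ok and total > best_score:
                best_score = total
                best_set = frozenset(comb)
    return best_set


def random_chain_instance(rng):
    """Planted chain with strictly decreasing overlaps + weak decoys."""
    n = int(rng.integers(5, 9))
    names = [f"r{i}" for i in range(n)] + ["x0", "x1"]
    edges = []
    ov = 5_000
    for i in range(n - 1):
        ov -= int(rng.integers(50, 200))
        edges.append((f"r{i}", "e", f"r{i+1}", "s", ov, int(ov * 0.8), 0.9, 40))
    # decoys scored far below any chain edge: endpoint attachments and
    # blocked internal connections
    edges.append(("r0", "s", "x0", "e", 300, 200, 0.3, 8))
    edges.append((f"r{n-1}", "e", "x1", "s", 250, 150, 0.3, 8))
    for _ in range(int(rng.integers(1, 4))):
        i, j = sorted(rng.choice(n, size=2, replace=False))
        if j - i < 2:
            continue
        edges.append((f"r{i}", "e", f"r{j}", "s", 200 + int(rng.integers(0, 50)),
                      100, 0.2, 6))
    return make_graph(names, edges)


class TestBuildLayout:
    def test_safe_chain_single_path(self):
        g = make_graph(
            "ABC",
            [
                ("A", "e", "B", "s", 1000, 800, 0.9, 40),
                ("B", "e", "C", "s", 900, 700, 0.9, 35),
            ],
        )
        layout = build_layout(g)
        assert [n for n, _ in layout.paths[0]] == ["A", "B", "C"]
        assert len(layout.paths) == 1

    def test_cycle_edge_rejected(self):
        g = make_graph(
            "ABC",
            [
                ("A", "e", "B", "s", 1000, 800, 0.9, 40),
                ("B", "e", "C", "s", 900, 700, 0.9, 35),
                ("C", "e", "A", "s", 800, 600, 0.9, 30),  # would close the cycle
            ],
        )
        layout = build_layout(g)
        selected = {e.key() for p in layout.path_edges for e in p}
        assert len(selected) == 2
        assert len(layout.paths) == 1

    def test_matching_property_on_simulation(self):
        genome = simulate_genome(10_000, 0.5, seed=73)
        cfg = SimulationConfig(
            mean_len=1_500, sd_len=300, subst_rate=0, indel_rate=0, depth=15, seed=74
        )
        reads = simulate_reads(genome, cfg)
        from olcasm.overlap_graph import build_graph

        g = build_graph(reads)
        layout = build_layout(g)
        seen_vertices = set()
        for edges in layout.path_edges:
            for e in edges:
                assert e.u not in seen_vertices and e.v not in seen_vertices
                seen_vertices.add(e.u)
                seen_vertices.add(e.v)
        emb = g.embedded_names
        placed = [n for p in layout.paths for n, _ in p]
        assert sorted(placed) == sorted(n for n in g.reads if n not in emb)

    def test_greedy_matches_exhaustive_on_planted_chains(self):
        rng = np.random.default_rng(75)
        model = EdgeFeatureModel(
            overlap_mu=3_000, overlap_sigma=1_500, csk_mu=2_400, csk_sigma=1_200,
            alpha=2.0, beta=1.0,
        )
        for _ in range(8):
            g = random_chain_instance(rng)
            for e in g.edges:
                edge_log_likelihood(e, model)
            layout = build_layout(g, safe=set(), model=model)
            got = {e.key() for p in layout.path_edges for e in p}
            want = {g.edges[i].key() for i in brute_force_best_matching(g)}
            assert got == want

    def test_error_free_simulation_yields_single_true_order_path(self):
        genome = simulate_genome(20_000, 0.5, seed=76)
        cfg = SimulationConfig(
            mean_len=2_000, sd_len=500, subst_rate=0, indel_rate=0, depth=30, seed=77
        )
        reads = simulate_reads(genome, cfg)
        from olcasm.overlap_graph import build_graph

        g = build_graph(reads)
        layout = build_layout(g)
        nonsingleton = layout.nonsingleton_paths
        assert len(nonsingleton) == 1
        starts = [parse_read_truth(n).start for n, _ in nonsingleton[0]]
        assert starts == sorted(starts) or starts == sorted(starts, reverse=True)
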