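"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own search code paths:
string alignment is a textbook O(nm) dynamic program, graph-restricted
optima come from Bellman-Ford over an explicitly materialized alignment
graph (networkx), and chains come from exhaustive enumeration.
"""

from __future__ import annotations

import random

import networkx as nx
import pytest

from sgalign.anchoring import Anchor
from sgalign.graph import AssemblyGraph, GraphPosition


# -- string-level oracles --------------------------------------------------


def dp_linear_cost(a: str, b: str, mu: float, sigma: float) -> float:
    """Classical global alignment cost with linear gaps (match 0)."""
    n, m = len(a), len(b)
    prev = [sigma * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [sigma * i] + [0.0] * m
        for j in range(1, m + 1):
            sub = prev[j - 1] + (0.0 if a[i - 1] == b[j - 1] else mu)
            cur[j] = min(sub, prev[j] + sigma, cur[j - 1] + sigma)
        prev = cur
    return prev[m]


def dp_semiglobal_cost(label: str, sub: str, mu: float, sigma: float) -> float:
    """Min cost aligning all of ``sub`` to any prefix of ``label``."""
    n, m = len(label), len(sub)
    prev = [sigma * j for j in range(m + 1)]
    best = prev[m]
    for i in range(1, n + 1):
        cur = [0.0] * (m + 1)
        cur[0] = sigma * i
        for j in range(1, m + 1):
            sub_c = prev[j - 1] + (0.0 if label[i - 1] == sub[j - 1] else mu)
            cur[j] = min(sub_c, prev[j] + sigma, cur[j - 1] + sigma)
        best = min(best, cur[m])
        prev = cur
    return best


# -- explicit alignment-graph oracle --------------------------------------


def explicit_product_cost(
    g: AssemblyGraph,
    sub: str,
    p1: GraphPosition,
    p2: GraphPosition | None,
    mu: float,
    sigma: float,
) -> float:
    """Bellman-Ford over the fully materialized alignment graph.

    Returns the optimal cost from <p1, 0> to <p2, |sub|> (or to any state at
    query position |sub| when ``p2`` is None); ``inf`` when unreachable.
    """
    n = len(sub)
    sg = nx.DiGraph()
    for eid, label in g.edges.items():
        L = len(label)
        for i in range(L + 1):
            for j in range(n + 1):
                u = (eid, i, j)
                if i < L:
                    sg.add_edge(u, (eid, i + 1, j), weight=sigma)
                    if j < n:
                        w = 0.0 if (label[i] == sub[j] and label[i] != "N") else mu
                        sg.add_edge(u, (eid, i + 1, j + 1), weight=w)
                if j < n:
                    sg.add_edge(u, (eid, i, j + 1), weight=sigma)
                if i == L:
                    for to, ovl in g.out_links[eid]:
                        sg.add_edge(u, (to, ovl, j), weight=0.0)
    source = (p1.edge, p1.offset, 0)
    if source not in sg:
        sg.add_node(source)
    lengths = nx.single_source_bellman_ford_path_length(sg, source)
    if p2 is not None:
        return lengths.get((p2.edge, p2.offset, n), float("inf"))
    finals = [d for (e, i, j), d in lengths.items() if j == n]
    return min(finals) if finals else float("inf")


# -- random instances ------------------------------------------------------


def random_graph(
    rng: random.Random,
    max_segments: int = 4,
    max_label: int = 15,
    with_overlaps: bool = True,
) -> AssemblyGraph:
    """A random small valid assembly graph (<= 2*max_segments edges)."""
    g = AssemblyGraph()
    n_seg = rng.randint(1, max_segments)
    for s in range(n_seg):
        length = rng.randint(3, max_label)
        g.add_segment(f"s{s}", "".join(rng.choice("ACGT") for _ in range(length)))
    names = g.segment_names()
    for _ in range(rng.randint(0, 2 * n_seg)):
        a = rng.choice(names) + rng.choice("+-")
        b = rng.choice(names) + rng.choice("+-")
        ovl = 0
        if with_overlaps:
            max_ovl = min(2, g.length(a) - 1, g.length(b) - 1)
            for cand in range(max_ovl, 0, -1):  # largest consistent overlap
                if g.edges[a][-cand:] == g.edges[b][:cand]:
                    ovl = cand
                    break
        g.add_link(a, b, ovl)
    return g


def random_position(rng: random.Random, g: AssemblyGraph, min_in_ovl: bool = False):
    eid = rng.choice(sorted(g.edges))
    lo = max((ovl for _, ovl in g.in_links[eid]), default=0) if min_in_ovl else 0
    return GraphPosition(eid, rng.randint(lo, g.length(eid)))


def brute_force_chain_weight(g, anchors, alpha: float) -> float:
    """Maximum chain weight by exhaustive DFS over ordered subsets."""
    from sgalign.chaining import chain_gap_distance

    order = sorted(anchors, key=lambda a: (a.start_s, a.edge, a.start_e))
    best = 0.0

    def rec(idx: int, last, weight: float) -> None:
        nonlocal best
        best = max(best, weight)
        for i in range(idx, len(order)):
            a = order[i]
            if last is None or chain_gap_distance(g, last, a, alpha) is not None:
                rec(i + 1, a, weight + a.weight)

    rec(0, None, 0.0)
    return best


# -- fixtures --------------------------------------------------------------


@pytest.fixture(scope="session")
def overlap_chain_graph() -> AssemblyGraph:
    """Two segments AAAC -> ACGG overlapping by 2 (spells AAACGG)."""
    g = AssemblyGraph()
    g.add_segment("a", "AAAC")
    g.add_segment("b", "ACGG")
    g.add_link("a+", "b+", 2)
    return g


@pytest.fixture(scope="session")
def bubble_graph() -> AssemblyGraph:
    """pre -> {short(3bp) | long(5bp)} -> post, no overlaps."""
    g = AssemblyGraph()
    g.add_segment("pre", "ACGTACGT")
    g.add_segment("short", "TTT")
    g.add_segment("long", "GGGGG")
    g.add_segment("post", "CATGCATG")
    for b in ("short", "long"):
        g.add_link("pre+", b + "+", 0)
        g.add_link(b + "+", "post+", 0)
    return g


@pytest.fixture(scope="session")
def small_bundle():
    """A 20 kb simulated genome with its graph, map and annotations."""
    from sgalign.simulate import (
        SimulationConfig,
        build_compacted_dbg,
        simulate_genome,
    )

    cfg = SimulationConfig(
        genome_length=20_000,
        repeat_count=2,
        repeat_length=300,
        read_count=20,
        protein_count=5,
        k=21,
        seed=7,
    )
    genome, ann = simulate_genome(cfg)
    g, gmap = build_compacted_dbg(genome, cfg.k)
    return cfg, genome, ann, g, gmap


def make_anchor(qs, qe, edge, es, ee) -> Anchor:
    return Anchor(qs, qe, edge, es, ee)
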