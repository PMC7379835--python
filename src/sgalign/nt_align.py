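"""Nucleotide sequence-to-graph alignment.

The optimal path connecting (or extending) anchor positions is found by a
shortest-path search over the implicit alignment graph ``SG(G, Sub)``: states
are pairs of a graph position and a query position, and weighted edges encode
graph-character deletion (sigma), query-character insertion (sigma), and
diagonal match/mismatch (0 / mu) moves, with zero-weight edges crossing graph
vertices.  With non-negative weights Dijkstra applies; for the unit-cost
(edit distance) scheme a 0-1 BFS over a double-ended queue reaches the same
optimum while only ever handling weights 0 and 1.  The product graph is
never materialized: successors are generated lazily.
"""

from __future__ import annotations

import heapq
import logging
from collections import deque
from dataclasses import dataclass, field

import edlib

from .engine import AlignmentNotFound, SearchLimitExceeded, SearchLimits
from .graph import (
    AssemblyGraph,
    GraphPath,
    GraphPosition,
    extract_neighborhood,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringScheme:
    """Linear-gap scheme: match 0, mismatch ``mu``, gap ``sigma`` per base."""

    mu: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.mu < 0 or self.sigma <= 0:
            raise ValueError("require mu >= 0 and sigma > 0")


@dataclass
class AlignmentResult:
    """A graph path aligned to a query fragment.

    ``cigar`` is an extended edit transcript over ``= X I D`` (query-centric:
    ``I`` consumes query only, ``D`` consumes graph only), run-length encoded.
    """

    path: GraphPath | None
    cost: float
    query_range: tuple[int, int]
    cigar: str
    identity: float
    ops: str = field(default="", repr=False)  # un-encoded transcript


def encode_cigar(ops: str) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def transcript_cost(ops: str, sc: ScoringScheme) -> float:
    return sum(
        sc.mu if o == "X" else sc.sigma if o in "ID" else 0.0 for o in ops
    )


def compute_identity(result: AlignmentResult) -> float:
    """Fraction of alignment columns that are matches."""
    if not result.ops:
        return 0.0
    return result.ops.count("=") / len(result.ops)


def is_mapped(s_len: int, result: AlignmentResult, threshold: float = 0.8) -> bool:
    """A query is mapped if one alignment path covers >= ``threshold`` of it."""
    a, b = result.query_range
    return (b - a) >= threshold * s_len


# -- the implicit product-graph search ------------------------------------


def _equivalent_positions(g: AssemblyGraph, pos: GraphPosition) -> set[GraphPosition]:
    """Positions physically identical to ``pos``.

    An offset inside the overlap consumed by an incoming link also exists
    near the end of the predecessor edge; searches that travel through the
    predecessor must be allowed to stop there.
    """
    out = {pos}
    frontier = [pos]
    while frontier:
        cur = frontier.pop()
        for prev, ovl in g.in_links[cur.edge]:
            if cur.offset < ovl:
                eq = GraphPosition(prev, g.length(prev) - ovl + cur.offset)
                if eq not in out:
                    out.add(eq)
                    frontier.append(eq)
    return out


def _search(
    g: AssemblyGraph,
    sub: str,
    start: GraphPosition,
    target: GraphPosition | None,
    sc: ScoringScheme,
    limits: SearchLimits,
    engine: str,
):
    """Shortest path in SG(G, sub) from <start, 0>.

    ``target`` fixes the graph end position (fill mode); ``None`` accepts any
    graph position at query position ``|sub|`` (extension mode).  Returns
    ``(cost, end_state, pred)`` for traceback.
    """
    n = len(sub)
    use_deque = engine == "zero_one_bfs" or (
        engine == "auto" and sc.mu == 1 and sc.sigma == 1
    )
    if engine == "zero_one_bfs" and not (sc.mu == 1 and sc.sigma == 1):
        raise ValueError("zero_one_bfs requires mu = sigma = 1")

    goal_states: set[tuple[str, int, int]] | None = None
    if target is not None:
        goal_states = {
            (p.edge, p.offset, n) for p in _equivalent_positions(g, target)
        }

    start_state = (start.edge, start.offset, 0)
    dist: dict[tuple[str, int, int], float] = {start_state: 0.0}
    pred: dict[tuple[str, int, int], tuple[tuple[str, int, int], str]] = {}
    if use_deque:
        dq: deque[tuple[float, tuple[str, int, int]]] = deque([(0.0, start_state)])
    else:
        counter = 0
        heap: list[tuple[float, int, tuple[str, int, int]]] = [(0.0, 0, start_state)]
    settled = 0
    cap = limits.cost_cap

    def relax(state, nstate, w, op, d):
        nd = d + w
        if cap is not None and nd > cap:
            return
        if nd < dist.get(nstate, float("inf")):
            dist[nstate] = nd
            pred[nstate] = (state, op)
            if use_deque:
                if w == 0:
                    dq.appendleft((nd, nstate))
                else:
                    dq.append((nd, nstate))
            else:
                nonlocal counter
                counter += 1
                heapq.heappush(heap, (nd, counter, nstate))

    while (dq if use_deque else heap):
        if use_deque:
            d, state = dq.popleft()
        else:
            d, _, state = heapq.heappop(heap)
        if d > dist.get(state, float("inf")):
            continue
        eid, i, j = state
        if goal_states is not None:
            if state in goal_states:
                return d, state, pred
        elif j == n:
            return d, state, pred
        settled += 1
        if settled > limits.max_states:
            raise SearchLimitExceeded(
                f"state budget {limits.max_states} exhausted"
            )
        label = g.edges[eid]
        elen = len(label)
        # Preference order (ties): diagonal > deletion > insertion; vertex
        # crossings are free and taken eagerly.
        if i == elen:
            for to, ovl in g.out_links[eid]:
                relax(state, (to, ovl, j), 0.0, "C", d)
        else:
            if j < n:
                gchar = label[i]
                w = 0.0 if (gchar == sub[j] and gchar != "N") else sc.mu
                relax(state, (eid, i + 1, j + 1), w, "=" if w == 0 else "X", d)
            relax(state, (eid, i + 1, j), sc.sigma, "D", d)
        if j < n:
            relax(state, (eid, i, j + 1), sc.sigma, "I", d)
    raise AlignmentNotFound("no connecting path within limits")


def _traceback(
    g: AssemblyGraph,
    start: GraphPosition,
    end_state: tuple[str, int, int],
    pred,
) -> tuple[GraphPath, str]:
    ops_rev: list[str] = []
    edges_rev: list[str] = [end_state[0]]
    state = end_state
    start_state = (start.edge, start.offset, 0)
    while state != start_state:
        prev, op = pred[state]
        if op == "C":
            edges_rev.append(prev[0])
        else:
            ops_rev.append(op)
        state = prev
    edges = list(reversed(edges_rev))
    path = GraphPath(
        edges,
        GraphPosition(edges[0], start.offset),
        GraphPosition(edges[-1], end_state[1]),
    )
    return path, "".join(reversed(ops_rev))


def _result_from(path: GraphPath, ops: str, sc: ScoringScheme, qlen: int) -> AlignmentResult:
    res = AlignmentResult(
        path=path,
        cost=transcript_cost(ops, sc),
        query_range=(0, qlen),
        cigar=encode_cigar(ops),
        identity=0.0,
        ops=ops,
    )
    res.identity = compute_identity(res)
    return res


def dijkstra_product(
    g: AssemblyGraph,
    sub: str,
    p1: GraphPosition,
    p2: GraphPosition | None,
    sc: ScoringScheme,
    limits: SearchLimits | None = None,
) -> AlignmentResult:
    """Dijkstra over the implicit alignment graph (any non-negative scheme)."""
    limits = limits or SearchLimits()
    cost, end_state, pred = _search(g, sub, p1, p2, sc, limits, "dijkstra")
    path, ops = _traceback(g, p1, end_state, pred)
    res = _result_from(path, ops, sc, len(sub))
    assert abs(res.cost - cost) < 1e-9
    return res


def zero_one_bfs(
    g: AssemblyGraph,
    sub: str,
    p1: GraphPosition,
    p2: GraphPosition | None,
    sc: ScoringScheme | None = None,
    limits: SearchLimits | None = None,
) -> AlignmentResult:
    """Deque-based shortest path; valid only for the unit-cost scheme."""
    sc = sc or ScoringScheme(1, 1)
    limits = limits or SearchLimits()
    cost, end_state, pred = _search(g, sub, p1, p2, sc, limits, "zero_one_bfs")
    path, ops = _traceback(g, p1, end_state, pred)
    res = _result_from(path, ops, sc, len(sub))
    assert abs(res.cost - cost) < 1e-9
    return res


def fill_between(
    g: AssemblyGraph,
    sub: str,
    p1: GraphPosition,
    p2: GraphPosition,
    sc: ScoringScheme | None = None,
    limits: SearchLimits | None = None,
    engine: str = "auto",
) -> AlignmentResult:
    """Minimum-cost path from ``p1`` to ``p2`` aligning ``sub`` on the way.

    The returned cost equals the linear-gap alignment cost between the
    path's label and ``sub``.  Raises :class:`AlignmentNotFound` if no
    connecting path exists within the limits.
    """
    sc = sc or ScoringScheme(1, 1)
    limits = limits or SearchLimits()
    if p1 == p2 and not sub:
        path = GraphPath([p1.edge], p1, p1)
        return _result_from(path, "", sc, 0)
    cost, end_state, pred = _search(g, sub, p1, p2, sc, limits, engine)
    path, ops = _traceback(g, p1, end_state, pred)
    return _result_from(path, ops, sc, len(sub))


def extend_terminal(
    g: AssemblyGraph,
    suf: str,
    p_s: GraphPosition,
    direction: str = "right",
    sc: ScoringScheme | None = None,
    limits: SearchLimits | None = None,
    engine: str = "auto",
) -> AlignmentResult:
    """Semi-global extension of a query fragment beyond a fixed position.

    ``direction='right'`` aligns ``suf`` starting at ``p_s``; ``'left'``
    aligns ``suf`` *ending* at ``p_s`` and is implemented by running the
    forward engine on the reverse-complement graph with the reversed
    complemented fragment.
    """
    sc = sc or ScoringScheme(1, 1)
    limits = limits or SearchLimits()
    if direction == "left":
        from .graph import revcomp

        rc_res = extend_terminal(
            g, revcomp(suf), g.rc_position(p_s), "right", sc, limits, engine
        )
        if rc_res.path is None:
            return rc_res
        path = g.rc_path(rc_res.path)
        ops = rc_res.ops[::-1]
        return _result_from(path, ops, sc, len(suf))
    if not suf:
        path = GraphPath([p_s.edge], p_s, p_s)
        return _result_from(path, "", sc, 0)
    cost, end_state, pred = _search(g, suf, p_s, None, sc, limits, engine)
    path, ops = _traceback(g, p_s, end_state, pred)
    return _result_from(path, ops, sc, len(suf))


# -- top-level nucleotide pipeline ----------------------------------------


@dataclass
class NtParams:
    """Tunables of the nucleotide pipeline (defaults follow the tool's
    standard configuration: unit costs, t=200, T=500, alpha=1.3)."""

    k_seed: int = 14
    min_span: int | None = None  # default: the graph's de Bruijn k
    t: int = 200
    T: int = 500
    alpha: float = 1.3
    scheme: ScoringScheme = ScoringScheme(1.0, 1.0)
    mapped_threshold: float = 0.8
    max_states: int = 5_000_000
    # terminal extensions are abandoned when their cost exceeds this fraction
    # of the fragment length (times sigma): more diverged tails stay unaligned
    max_tail_divergence: float = 0.35
    engine: str = "auto"


def _edlib_ops(q: str, tgt: str) -> str:
    """Edit transcript (=XID, query-centric) between two strings via edlib."""
    if q == tgt:
        return "=" * len(q)
    res = edlib.align(q, tgt, mode="NW", task="path")
    ops = []
    for count, op in _parse_cigar(res["cigar"]):
        ops.append(op * count)
    s = "".join(ops)
    # edlib's I consumes the query, D the target -- same as our convention;
    # verify and flip if an edlib release ever changes that.
    nq = sum(1 for o in s if o in "=XI")
    nt_ = sum(1 for o in s if o in "=XD")
    if nq != len(q) or nt_ != len(tgt):
        s = s.translate(str.maketrans("ID", "DI"))
    return s


def _parse_cigar(cig: str):
    num = ""
    for ch in cig:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _anchor_ops(g, s: str, a) -> str:
    return _edlib_ops(s[a.start_s : a.end_s], g.edges[a.edge][a.start_e : a.end_e])


def align_nt_query(
    g: AssemblyGraph,
    s: str,
    params: NtParams | None = None,
    index=None,
) -> list[AlignmentResult]:
    """Full pipeline: seed, filter, chain, fill, extend.

    Returns the best alignment for the query (a single-element list), or an
    empty list when the query has no surviving anchors.
    """
    from .anchoring import filter_anchors, find_anchors
    from .chaining import heaviest_chain

    params = params or NtParams()
    s = s.upper()
    anchors = find_anchors(
        g, s, k_seed=params.k_seed, min_span=params.min_span, index=index
    )
    filtered = filter_anchors(anchors, len(s), g, T=params.T, t=params.t)
    chain = heaviest_chain(g, filtered, alpha=params.alpha)
    if not chain.anchors:
        return []
    result = _assemble(g, s, chain.anchors, params)
    return [result] if result is not None else []


def _assemble(g, s, anchors, params) -> AlignmentResult | None:
    sc = params.scheme
    # fill between consecutive skeleton anchors; on an irrecoverable gap,
    # keep the heavier side of the skeleton and retry
    pieces: list[str] = []  # transcripts per segment
    edges: list[str] = [anchors[0].edge]
    for i, a in enumerate(anchors):
        if i > 0:
            prev = anchors[i - 1]
            sub = s[prev.end_s : a.start_s]
            p1 = GraphPosition(prev.edge, prev.end_e)
            p2 = GraphPosition(a.edge, a.start_e)
            try:
                fill = _run_fill(g, sub, p1, p2, params)
            except AlignmentNotFound:
                logger.debug("fill failed between anchors %d/%d; cutting chain", i - 1, i)
                left_w = sum(x.weight for x in anchors[:i])
                right_w = sum(x.weight for x in anchors[i:])
                side = anchors[:i] if left_w >= right_w else anchors[i:]
                return _assemble(g, s, side, params)
            pieces.append(fill.ops)
            edges.extend(fill.path.edges[1:])
            if fill.path.end != p2:
                edges.append(a.edge)  # fill stopped on an equivalent position
        pieces.append(_anchor_ops(g, s, a))

    first, last = anchors[0], anchors[-1]
    q_start, q_end = first.start_s, last.end_s
    start_pos = GraphPosition(first.edge, first.start_e)
    end_pos = GraphPosition(last.edge, last.end_e)

    left_frag = s[: first.start_s]
    if left_frag:
        ext = _run_extend(g, left_frag, start_pos, "left", params)
        if ext is not None:
            pieces.insert(0, ext.ops)
            edges = ext.path.edges[:-1] + edges
            start_pos = ext.path.start
            q_start = 0
    right_frag = s[last.end_s :]
    if right_frag:
        ext = _run_extend(g, right_frag, end_pos, "right", params)
        if ext is not None:
            pieces.append(ext.ops)
            edges = edges + ext.path.edges[1:]
            end_pos = ext.path.end
            q_end = len(s)

    ops = "".join(pieces)
    path = GraphPath(edges, start_pos, end_pos)
    res = AlignmentResult(
        path=path,
        cost=transcript_cost(ops, sc),
        query_range=(q_start, q_end),
        cigar=encode_cigar(ops),
        identity=0.0,
        ops=ops,
    )
    res.identity = compute_identity(res)
    return res


def _run_fill(g, sub, p1, p2, params) -> AlignmentResult:
    radius = params.alpha * len(sub) + 2 * params.t
    ng = extract_neighborhood(g, [p1, p2], radius)
    # upper bound on the optimal cost: delete the whole connecting path
    # (<= alpha*|sub| by chain compatibility) and insert the whole fragment
    cap = params.scheme.sigma * (1 + params.alpha) * len(sub) + 4 * params.scheme.sigma
    limits = SearchLimits(max_states=params.max_states, cost_cap=cap)
    return fill_between(ng, sub, p1, p2, params.scheme, limits, params.engine)


def _run_extend(g, frag, pos, direction, params) -> AlignmentResult | None:
    radius = params.alpha * len(frag) + 2 * params.t
    ng = extract_neighborhood(g, [pos], radius)
    cap = max(
        20 * params.scheme.sigma,
        params.max_tail_divergence * params.scheme.sigma * len(frag),
    )
    limits = SearchLimits(max_states=params.max_states, cost_cap=cap)
    try:
        return extend_terminal(ng, frag, pos, direction, params.scheme, limits, params.engine)
    except AlignmentNotFound:
        logger.debug("%s extension of %d bp abandoned", direction, len(frag))
        return None
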