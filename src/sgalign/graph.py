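"""Assembly-graph data model and GFA 1.x I/O.

The graph is a directed, edge-labeled graph in the style of a compacted de
Bruijn graph: every GFA segment contributes two directed edges (one per
orientation), each carrying a nucleotide label, and every GFA link connects
the end of one oriented edge to the start of another with an optional
``<int>M`` overlap that is trimmed from the successor when concatenating
labels.  Positions live *between* characters: a :class:`GraphPosition`
``(e, i)`` with ``0 <= i <= |e|`` points just before the ``i``-th character
of the label of edge ``e``.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

INF = math.inf


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rc_edge_id(edge_id: str) -> str:
    """Flip the orientation suffix of an oriented edge id (``u1+`` <-> ``u1-``)."""
    if edge_id.endswith("+"):
        return edge_id[:-1] + "-"
    if edge_id.endswith("-"):
        return edge_id[:-1] + "+"
    raise ValueError(f"edge id {edge_id!r} lacks an orientation suffix")


class GFAParseError(ValueError):
    pass


class GraphValidationError(ValueError):
    pass


class GraphPosition(NamedTuple):
    """A position between characters on an oriented edge: ``0 <= offset <= |e|``."""

    edge: str
    offset: int


@dataclass
class GraphPath:
    """A walk through consecutive edges with trimmed terminal offsets."""

    edges: list[str]
    start: GraphPosition
    end: GraphPosition

    def __post_init__(self) -> None:
        if self.edges:
            if self.start.edge != self.edges[0] or self.end.edge != self.edges[-1]:
                raise GraphValidationError("path endpoints must lie on terminal edges")


@dataclass
class AssemblyGraph:
    """Directed edge-labeled assembly graph with per-link overlaps.

    ``edges`` maps oriented edge ids to labels; ``out_links[e]`` lists
    ``(successor, overlap)`` pairs.  For every edge its reverse complement
    (under :func:`rc_edge_id`) is present, and links come in reverse
    complement pairs.
    """

    edges: dict[str, str] = field(default_factory=dict)
    out_links: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    in_links: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    k: int | None = None

    # -- construction -----------------------------------------------------

    def add_segment(self, name: str, seq: str) -> None:
        if not seq:
            raise GraphValidationError(f"segment {name!r} has an empty sequence")
        fwd, rev = name + "+", name + "-"
        self.edges[fwd] = seq.upper()
        self.edges[rev] = revcomp(seq.upper())
        for eid in (fwd, rev):
            self.out_links.setdefault(eid, [])
            self.in_links.setdefault(eid, [])

    def add_link(self, from_edge: str, to_edge: str, overlap: int = 0) -> None:
        for eid in (from_edge, to_edge):
            if eid not in self.edges:
                raise GraphValidationError(f"link references unknown edge {eid!r}")
        if overlap >= min(len(self.edges[from_edge]), len(self.edges[to_edge])):
            raise GraphValidationError(
                f"overlap {overlap} >= shorter segment for link "
                f"{from_edge}->{to_edge}"
            )
        if overlap and (
            self.edges[from_edge][-overlap:] != self.edges[to_edge][:overlap]
        ):
            # trimming is only meaningful when the sequences actually overlap
            raise GraphValidationError(
                f"link {from_edge}->{to_edge}: overlapping sequences disagree"
            )
        self._add_directed_link(from_edge, to_edge, overlap)
        self._add_directed_link(rc_edge_id(to_edge), rc_edge_id(from_edge), overlap)

    def _add_directed_link(self, a: str, b: str, overlap: int) -> None:
        # one link per oriented edge pair: the overlap must be unambiguous
        # for label concatenation, so duplicates are ignored
        if any(to == b for to, _ in self.out_links[a]):
            return
        self.out_links[a].append((b, overlap))
        self.in_links[b].append((a, overlap))

    # -- basic queries ----------------------------------------------------

    def label(self, edge_id: str) -> str:
        return self.edges[edge_id]

    def length(self, edge_id: str) -> int:
        return len(self.edges[edge_id])

    def rc(self, edge_id: str) -> str:
        return rc_edge_id(edge_id)

    def rc_position(self, pos: GraphPosition) -> GraphPosition:
        return GraphPosition(rc_edge_id(pos.edge), self.length(pos.edge) - pos.offset)

    def rc_path(self, path: GraphPath) -> GraphPath:
        edges = [rc_edge_id(e) for e in reversed(path.edges)]
        return GraphPath(edges, self.rc_position(path.end), self.rc_position(path.start))

    def overlap(self, a: str, b: str) -> int:
        for to, ovl in self.out_links[a]:
            if to == b:
                return ovl
        raise GraphValidationError(f"no link {a}->{b}")

    def segment_names(self) -> list[str]:
        return sorted({e[:-1] for e in self.edges})

    def total_label_length(self) -> int:
        return sum(len(s) for s in self.edges.values())

    def dump(self) -> str:
        """Deterministic textual listing of edges and links (test aid)."""
        lines = [f"E\t{eid}\t{self.edges[eid]}" for eid in sorted(self.edges)]
        for eid in sorted(self.out_links):
            for to, ovl in sorted(self.out_links[eid]):
                lines.append(f"L\t{eid}\t{to}\t{ovl}")
        return "\n".join(lines)


# -- GFA I/O ---------------------------------------------------------------


def load_gfa(path: str) -> AssemblyGraph:
    """Read a GFA 1.x file (S and L lines; other line types are ignored).

    Overlaps must be ``*`` (treated as 0) or a single ``<int>M`` operation.
    """
    g = AssemblyGraph()
    pending_links: list[tuple[int, str, str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3 or not fields[2] or fields[2] == "*":
                    raise GFAParseError(f"line {lineno}: malformed S line")
                g.add_segment(fields[1], fields[2])
            elif tag == "L":
                if len(fields) < 6:
                    raise GFAParseError(f"line {lineno}: malformed L line")
                _, a, ao, b, bo, cig = fields[:6]
                if ao not in "+-" or bo not in "+-":
                    raise GFAParseError(f"line {lineno}: bad orientation")
                if cig == "*":
                    ovl = 0
                elif cig.endswith("M") and cig[:-1].isdigit():
                    ovl = int(cig[:-1])
                else:
                    raise GFAParseError(
                        f"line {lineno}: unsupported overlap CIGAR {cig!r}"
                    )
                pending_links.append((lineno, a + ao, b + bo, ovl))
            elif tag in ("H",):
                for f in fields[1:]:
                    if f.startswith("k:i:"):  # non-standard, written by our simulator
                        g.k = int(f[4:])
            else:
                logger.warning("ignoring GFA line type %r at line %d", tag, lineno)
    for lineno, a, b, ovl in pending_links:
        try:
            g.add_link(a, b, ovl)
        except GraphValidationError as exc:
            raise GraphValidationError(f"line {lineno}: {exc}") from exc
    return g


def write_gfa(g: AssemblyGraph, path: str) -> None:
    """Write the graph as GFA 1.x (one S line per segment, forward links)."""
    with open(path, "w") as fh:
        if g.k is not None:
            fh.write(f"H\tVN:Z:1.0\tk:i:{g.k}\n")
        else:
            fh.write("H\tVN:Z:1.0\n")
        for name in g.segment_names():
            fh.write(f"S\t{name}\t{g.edges[name + '+']}\n")
        seen = set()
        for a in sorted(g.out_links):
            for b, ovl in sorted(g.out_links[a]):
                key = (a, b, ovl)
                rc_key = (rc_edge_id(b), rc_edge_id(a), ovl)
                if key in seen or rc_key in seen:
                    continue
                seen.add(key)
                fh.write(
                    f"L\t{a[:-1]}\t{a[-1]}\t{b[:-1]}\t{b[-1]}\t{ovl}M\n"
                )


# -- path labels -----------------------------------------------------------


def label_of_path(g: AssemblyGraph, p: GraphPath) -> str:
    """Concatenate edge labels along ``p`` with link overlaps trimmed.

    The successor of each link contributes only its label beyond the link
    overlap; the result is then clipped to ``[start.offset, end.offset)``.
    """
    if not p.edges:
        return ""
    if len(p.edges) == 1:
        if not 0 <= p.start.offset <= p.end.offset <= g.length(p.edges[0]):
            raise GraphValidationError("inconsistent offsets on single-edge path")
        return g.label(p.edges[0])[p.start.offset : p.end.offset]
    parts = [g.label(p.edges[0])[p.start.offset :]]
    for prev, cur in zip(p.edges, p.edges[1:]):
        ovl = g.overlap(prev, cur)  # raises if not linked
        parts.append(g.label(cur)[ovl:])
    tail_trim = g.length(p.edges[-1]) - p.end.offset
    s = "".join(parts)
    if tail_trim:
        if tail_trim > len(s):
            raise GraphValidationError("end offset before path start")
        s = s[:-tail_trim]
    return s


def path_length(g: AssemblyGraph, p: GraphPath) -> int:
    """Length in bp of ``Label(p)`` without materializing it."""
    if not p.edges:
        return 0
    total = g.length(p.edges[0]) - p.start.offset
    for prev, cur in zip(p.edges, p.edges[1:]):
        total += g.length(cur) - g.overlap(prev, cur)
    total -= g.length(p.edges[-1]) - p.end.offset
    return total


# -- distance queries ------------------------------------------------------


def min_graph_distance(
    g: AssemblyGraph, a: GraphPosition, b: GraphPosition, cap: float = INF
) -> float:
    """Shortest label-length distance (bp) from position ``a`` to ``b``.

    Returns 0 when the positions coincide in order on one edge, and ``inf``
    when no connecting path of length <= ``cap`` exists.  The search is a
    Dijkstra over edge-entry states and stops once the frontier exceeds
    ``cap``.
    """
    best = INF
    if a.edge == b.edge and a.offset <= b.offset:
        best = b.offset - a.offset
        if best == 0:
            return 0.0
    # dist[e] = min label-length from `a` to the *origin* (offset 0) of edge e,
    # where entering via a link of overlap `o` counts the first o characters of
    # e as already traversed (so dist[e] may be negative for the first hop).
    dist: dict[str, float] = {}
    heap: list[tuple[float, str]] = []
    exit_a = g.length(a.edge) - a.offset
    for to, ovl in g.out_links[a.edge]:
        d0 = exit_a - ovl
        if d0 < dist.get(to, INF):
            dist[to] = d0
            heapq.heappush(heap, (d0, to))
    while heap:
        d, e = heapq.heappop(heap)
        if d > dist.get(e, INF) or d > cap:
            if d > cap:
                break
            continue
        if e == b.edge:
            best = min(best, d + b.offset)
        exit_e = d + g.length(e)
        for to, ovl in g.out_links[e]:
            nd = exit_e - ovl
            if nd < dist.get(to, INF) and nd <= cap:
                dist[to] = nd
                heapq.heappush(heap, (nd, to))
    if best > cap:
        return INF
    return float(best)


def extract_neighborhood(
    g: AssemblyGraph, seeds: Iterable[GraphPosition], radius: float
) -> AssemblyGraph:
    """Subgraph of edges reachable within ``radius`` bp of any seed.

    Reachability is measured forward and backward by cumulative label length;
    the reverse complement of every retained edge is retained too, so the
    result is a valid :class:`AssemblyGraph`.
    """
    keep: set[str] = set()
    seeds = list(seeds)
    for pos in seeds:
        keep.add(pos.edge)
        keep |= _reach(g, pos, radius, forward=True)
        keep |= _reach(g, pos, radius, forward=False)
    keep |= {rc_edge_id(e) for e in keep}
    sub = AssemblyGraph(k=g.k)
    for eid in keep:
        sub.edges[eid] = g.edges[eid]
        sub.out_links.setdefault(eid, [])
        sub.in_links.setdefault(eid, [])
    for eid in keep:
        for to, ovl in g.out_links[eid]:
            if to in keep:
                sub._add_directed_link(eid, to, ovl)
    return sub


def _reach(g: AssemblyGraph, pos: GraphPosition, radius: float, forward: bool) -> set[str]:
    links = g.out_links if forward else g.in_links
    start_exit = (
        g.length(pos.edge) - pos.offset if forward else pos.offset
    )
    dist: dict[str, float] = {}
    heap: list[tuple[float, str]] = []
    for to, ovl in links[pos.edge]:
        d0 = start_exit - ovl
        if d0 <= radius and d0 < dist.get(to, INF):
            dist[to] = d0
            heapq.heappush(heap, (d0, to))
    out: set[str] = set()
    while heap:
        d, e = heapq.heappop(heap)
        if d > dist.get(e, INF):
            continue
        out.add(e)
        exit_e = d + g.length(e)
        for to, ovl in links[e]:
            nd = exit_e - ovl
            if nd <= radius and nd < dist.get(to, INF):
                dist[to] = nd
                heapq.heappush(heap, (nd, to))
    return out
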