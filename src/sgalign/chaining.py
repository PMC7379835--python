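"""Heaviest-chain selection over filtered anchors.

A chain is an ordered subset of anchors, strictly increasing along the
query, in which every consecutive pair is *compatible*: the second anchor
follows the first without query overlap and the minimal graph distance
between their facing endpoints does not exceed ``alpha`` times the query
gap.  The heaviest (maximum total span) chain becomes the skeleton of the
final alignment; gaps between its anchors are filled by the shortest-path
search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .anchoring import Anchor
from .graph import AssemblyGraph, GraphPosition, min_graph_distance

DEFAULT_ALPHA = 1.3


@dataclass
class Chain:
    anchors: list[Anchor] = field(default_factory=list)

    @property
    def total_weight(self) -> float:
        return sum(a.weight for a in self.anchors)


def chain_gap_distance(
    g: AssemblyGraph, a: Anchor, b: Anchor, alpha: float = DEFAULT_ALPHA
) -> float | None:
    """Graph distance between compatible anchors, or None if incompatible.

    ``b`` must follow ``a`` on the query without overlap, and the minimal
    graph distance from the end of ``a`` to the start of ``b`` must not
    exceed ``alpha`` times the query gap (with a zero query gap requiring
    zero graph distance).
    """
    if b.start_s < a.end_s:
        return None
    gap = b.start_s - a.end_s
    pa = GraphPosition(a.edge, a.end_e)
    pb = GraphPosition(b.edge, b.start_e)
    d = min_graph_distance(g, pa, pb, cap=alpha * gap)
    if d <= alpha * gap:
        return d
    return None


def compatible(
    g: AssemblyGraph, a: Anchor, b: Anchor, alpha: float = DEFAULT_ALPHA
) -> bool:
    return chain_gap_distance(g, a, b, alpha) is not None


def heaviest_chain(
    g: AssemblyGraph, anchors: list[Anchor], alpha: float = DEFAULT_ALPHA
) -> Chain:
    """Maximum-weight chain of pairwise-compatible anchors, by O(n^2) DP.

    Ties are broken by smaller total graph distance along the chain, then by
    the lexicographically smallest sequence of (sorted) anchor indices, so
    the result is deterministic.
    """
    if not anchors:
        return Chain([])
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].start_s, anchors[i].edge, anchors[i].start_e),
    )
    srt = [anchors[i] for i in order]
    n = len(srt)
    # per node: (weight, total_gap_distance, chain_index_tuple)
    best: list[tuple[float, float, tuple[int, ...]]] = [
        (srt[i].weight, 0.0, (i,)) for i in range(n)
    ]
    for i in range(n):
        for j in range(i):
            d = chain_gap_distance(g, srt[j], srt[i], alpha)
            if d is None:
                continue
            w = best[j][0] + srt[i].weight
            dist = best[j][1] + d
            chain = best[j][2] + (i,)
            cand = (w, dist, chain)
            if (w, -dist) > (best[i][0], -best[i][1]) or (
                w == best[i][0]
                and dist == best[i][1]
                and chain < best[i][2]
            ):
                best[i] = cand
    w0 = max(b[0] for b in best)
    d0 = min(b[1] for b in best if b[0] == w0)
    chain_idx = min(b[2] for b in best if b[0] == w0 and b[1] == d0)
    return Chain([srt[i] for i in chain_idx])
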