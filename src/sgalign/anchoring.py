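"""Anchor discovery and filtering.

Anchors are local high-identity matches between a query range and a range on
a single graph edge; they seed the alignment and, after filtering, form the
chaining input.  The built-in seeder finds exact k-mer hits against an index
of the edge labels, clusters them per edge by diagonal, and polishes each
cluster into one gapped anchor with edlib.  Externally computed anchors can
be imported from PAF and flow through the same filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib

from .graph import AssemblyGraph

logger = logging.getLogger(__name__)

DEFAULT_SEED_LENGTH = 14  # bp
DEFAULT_T = 500  # bp, span bound for the middle-of-long-edge rule
DEFAULT_T_MIN = 200  # bp, minimum surviving anchor span


@dataclass(frozen=True)
class Anchor:
    """A local match between ``query[start_s:end_s]`` and ``edge[start_e:end_e]``.

    ``frame`` is only set for amino-acid anchors, where the query range is in
    residues, the edge range in nucleotides, and ``frame = start_e % 3``.
    """

    start_s: int
    end_s: int
    edge: str
    start_e: int
    end_e: int
    frame: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError("bad query range")
        if not (0 <= self.start_e < self.end_e):
            raise ValueError("bad edge range")

    @property
    def span(self) -> int:
        return self.end_s - self.start_s

    @property
    def weight(self) -> float:
        return float(self.span)


class KmerIndex:
    """Exact k-mer index over all oriented edge labels of a graph."""

    def __init__(self, g: AssemblyGraph, k_seed: int = DEFAULT_SEED_LENGTH,
                 max_occ: int = 200):
        self.g = g
        self.k = k_seed
        self.max_occ = max_occ
        self.index: dict[str, list[tuple[str, int]]] = {}
        for eid in sorted(g.edges):
            label = g.edges[eid]
            for i in range(len(label) - k_seed + 1):
                kmer = label[i : i + k_seed]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((eid, i))
        # drop hyper-repetitive seeds
        self.index = {
            k: v for k, v in self.index.items() if len(v) <= max_occ
        }

    def hits(self, s: str):
        """Yield (query_pos, edge, edge_pos) for every exact k-mer hit."""
        k = self.k
        idx = self.index
        for i in range(len(s) - k + 1):
            for eid, p in idx.get(s[i : i + k], ()):
                yield i, eid, p


def _cluster_hits(hits, k: int, max_query_gap: int = 500):
    """Group per-edge seed hits into roughly collinear clusters.

    Hits sorted by query position join the current cluster while the query
    gap stays small and the diagonal drifts no faster than a generous indel
    rate would allow.
    """
    per_edge: dict[str, list[tuple[int, int]]] = {}
    for i, eid, p in hits:
        per_edge.setdefault(eid, []).append((i, p))
    clusters = []
    for eid in sorted(per_edge):
        pts = sorted(per_edge[eid])
        open_clusters: list[list[tuple[int, int]]] = []
        for i, p in pts:
            placed = False
            for cl in open_clusters:
                li, lp = cl[-1]
                if i - li > max_query_gap:
                    continue
                drift = abs((p - i) - (lp - li))
                if p >= lp and drift <= 0.3 * max(i - li, 1) + 30:
                    cl.append((i, p))
                    placed = True
                    break
            if not placed:
                open_clusters.append([(i, p)])
            open_clusters = open_clusters[-25:]
        clusters.extend((eid, cl) for cl in open_clusters)
    return clusters


def find_anchors(
    g: AssemblyGraph,
    s: str,
    k_seed: int = DEFAULT_SEED_LENGTH,
    min_span: int | None = None,
    max_divergence: float = 0.35,
    index: KmerIndex | None = None,
) -> list[Anchor]:
    """Find local high-identity matches between ``s`` and individual edges.

    Every exact occurrence of a >= ``k_seed`` bp substring of ``s`` in an
    edge label yields an anchor covering it.  Clusters whose edlib-verified
    divergence exceeds ``max_divergence`` are dropped.  Results are sorted by
    (query start, edge id).
    """
    if not s:
        raise ValueError("empty query")
    if min_span is None:
        min_span = g.k if g.k is not None else k_seed
    if index is None or index.k != k_seed:
        index = KmerIndex(g, k_seed)
    s = s.upper()
    anchors: list[Anchor] = []
    for eid, cl in _cluster_hits(index.hits(s), k_seed):
        qs, ps = cl[0]
        qe, pe = cl[-1]
        qe += k_seed
        pe += k_seed
        span = qe - qs
        if span < min_span or pe - ps <= 0:
            continue
        qseg = s[qs:qe]
        eseg = g.edges[eid][ps:pe]
        if qseg == eseg:
            dist = 0
        else:
            dist = edlib.align(qseg, eseg, mode="NW", task="distance")[
                "editDistance"
            ]
        if dist > max_divergence * span:
            continue
        anchors.append(Anchor(qs, qe, eid, ps, pe))
    anchors = sorted(set(anchors), key=lambda a: (a.start_s, a.edge, a.start_e))
    return anchors


# -- filtering -------------------------------------------------------------


def _covered_by(intervals: list[tuple[int, int]], a: int, b: int) -> int:
    """Total length of [a, b) covered by a union of intervals."""
    covered = 0
    for s, e in _merged(intervals):
        lo, hi = max(a, s), min(b, e)
        if hi > lo:
            covered += hi - lo
    return covered


def _merged(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def filter_anchors(
    anchors: list[Anchor],
    s_len: int,
    g: AssemblyGraph,
    T: int = DEFAULT_T,
    t: int = DEFAULT_T_MIN,
) -> list[Anchor]:
    """Discard unreliable and ambiguous anchors, in three ordered passes.

    1. Anchors "in the middle" of long edges spanning less than ``T`` bp:
       discard ``a`` when ``end_e-start_e + min(start_s, start_e) +
       min(s_len-end_s, |e|-end_e) > 3*(end_e-start_e)``.
    2. Anchors at least half of whose query range is covered by other
       anchors; among a mutually covering set one representative (largest
       span, then smallest edge id) is kept.
    3. Anchors spanning less than ``t`` bp.

    Survivors are returned in input order; the filter is idempotent.
    """
    stage1 = []
    for a in anchors:
        span_e = a.end_e - a.start_e
        lhs = (
            span_e
            + min(a.start_s, a.start_e)
            + min(s_len - a.end_s, g.length(a.edge) - a.end_e)
        )
        if lhs > 3 * span_e and a.span < T:
            continue
        stage1.append(a)

    # greedy priority sweep realizes the keep-one-representative tie-break
    order = sorted(
        range(len(stage1)),
        key=lambda i: (-stage1[i].span, stage1[i].edge, stage1[i].start_s),
    )
    kept_ranges: list[tuple[int, int]] = []
    kept_idx: set[int] = set()
    for i in order:
        a = stage1[i]
        if _covered_by(kept_ranges, a.start_s, a.end_s) * 2 >= a.span:
            continue
        kept_idx.add(i)
        kept_ranges.append((a.start_s, a.end_s))
    stage2 = [a for i, a in enumerate(stage1) if i in kept_idx]

    return [a for a in stage2 if a.span >= t]


# -- external anchors ------------------------------------------------------


def read_paf(path: str, g: AssemblyGraph) -> dict[str, list[Anchor]]:
    """Read externally computed anchors from a PAF file.

    Target names are segment names; a ``-`` strand record is mapped onto the
    reverse-complement edge with its coordinates flipped, so downstream
    filtering treats imported and internal anchors identically.
    """
    out: dict[str, list[Anchor]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                raise ValueError(f"PAF line {lineno}: too few columns")
            qname, _, qs, qe, strand, tname = f[0], f[1], int(f[2]), int(f[3]), f[4], f[5]
            tlen, ts, te = int(f[6]), int(f[7]), int(f[8])
            if strand == "+":
                edge, es, ee = tname + "+", ts, te
            else:
                edge, es, ee = tname + "-", tlen - te, tlen - ts
            if edge not in g.edges:
                logger.warning("PAF line %d: unknown segment %r", lineno, tname)
                continue
            out.setdefault(qname, []).append(Anchor(qs, qe, edge, es, ee))
    for name in out:
        out[name].sort(key=lambda a: (a.start_s, a.edge, a.start_e))
    return out
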