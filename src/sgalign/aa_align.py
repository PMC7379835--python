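"""Protein-to-assembly-graph alignment through a frame-state alignment graph.

An amino-acid query is aligned against *AA-paths*: graph paths whose
nucleotide label translates, in the chosen reading frame, into a protein
with no stop codon.  The search runs over states ``<p, j, fs>`` where ``p``
is a graph position, ``j`` a query position and ``fs`` a 0-2 nt partial
codon buffer.  Moves either accumulate a base into ``fs`` (free), delete a
completed codon (gap cost sigma), consume a query residue against a
completed codon (substitution cost ``-M[aa_g, aa_q]``), insert a query
residue between codons (sigma), or cross a graph vertex (free).

Substitution scores come from a BLOSUM-style matrix ``M`` (default
BLOSUM90); since good alignments have *high* scores, costs are ``M' = -M``,
which is negative for good matches.  Adding a constant ``C > max(M)`` to
every query-consuming edge makes all weights non-negative, so Dijkstra
applies; every source-to-sink path shifts by exactly ``|query| * C``, so the
optimum is unchanged.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .anchoring import Anchor
from .engine import AlignmentNotFound, SearchLimitExceeded, SearchLimits
from .graph import (
    AssemblyGraph,
    GraphPath,
    GraphPosition,
    extract_neighborhood,
    label_of_path,
    revcomp,
)

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_AA = 5.0
DEFAULT_MATRIX = "BLOSUM90"

# -- genetic code ----------------------------------------------------------

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

_CANONICAL: dict[str, str] = {}
for _codon in sorted(CODON_TABLE):  # A < C < G < T
    _aa = CODON_TABLE[_codon]
    _CANONICAL.setdefault(_aa, _codon)


def translate(nt: str) -> str:
    """Translate a nucleotide string (length divisible by 3); N gives X."""
    if len(nt) % 3:
        raise ValueError("length not divisible by 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3].upper()
        aa = CODON_TABLE.get(codon)
        if aa is None:
            if set(codon) <= set("ACGTN"):
                aa = "X"
            else:
                raise ValueError(f"unknown codon {codon!r}")
        out.append(aa)
    return "".join(out)


def canonical_codon(aa: str) -> str:
    """Lexicographically minimal codon of a residue (A < C < G < T)."""
    try:
        return _CANONICAL[aa.upper()]
    except KeyError:
        raise ValueError(f"unknown residue {aa!r}") from None


def encode_canonical(protein: str) -> str:
    """Nucleotide encoding of a protein by lexicographically minimal codons."""
    return "".join(canonical_codon(a) for a in protein)


def _codon_aa(codon: str) -> str:
    aa = CODON_TABLE.get(codon)
    if aa is None:
        aa = "X"
    return aa


# -- scoring ---------------------------------------------------------------


def load_matrix(name_or_path: str):
    """A substitution matrix by bundled name (BLOSUM90, BLOSUM62, ...) or
    from an NCBI-style matrix file."""
    try:
        return substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        pass
    return substitution_matrices.read(name_or_path)


@dataclass
class AAScoringScheme:
    """Substitution matrix scoring with linear (per-codon) gap cost.

    ``C`` is the non-negativity shift; any value exceeding ``max(M)`` yields
    the same optimal paths.
    """

    matrix: object = None
    sigma: float = DEFAULT_SIGMA_AA
    C: float | None = None

    def __post_init__(self) -> None:
        if self.matrix is None:
            self.matrix = substitution_matrices.load(DEFAULT_MATRIX)
        if self.C is None:
            self.C = float(self.matrix.max()) + 1.0
        if self.C <= self.matrix.max():
            raise ValueError("shift constant C must exceed max(M)")
        self._alphabet = set(self.matrix.alphabet)

    def score(self, a: str, b: str) -> float:
        """Matrix score M[a, b]; residues outside the alphabet become X."""
        if a not in self._alphabet:
            a = "X"
        if b not in self._alphabet:
            b = "X"
        return float(self.matrix[a, b])

    def cost(self, a: str, b: str) -> float:
        return -self.score(a, b)


# -- the frame-state search ------------------------------------------------


@dataclass
class AAPathResult:
    """Raw engine output: an AA-path with its weights and transcript."""

    path: GraphPath
    ops: str  # residue-level transcript over = X I D
    weight: float  # un-shifted alignment cost (sum of M' and sigma terms)
    shifted_weight: float  # as searched in SG'
    nt_consumed: int


def _aa_search(
    g: AssemblyGraph,
    sub: str,
    start: GraphPosition,
    target: GraphPosition | None,
    sc: AAScoringScheme,
    limits: SearchLimits,
    transform,
    allow_deleted_stops: bool = False,
):
    """Dijkstra over the shifted frame-state alignment graph SG'.

    ``transform`` maps an accumulated base triple to the codon to translate
    (identity for rightward search; reverse complement when running leftward
    on the reverse-complement graph, where codons are built as suffixes).
    Terminates at query position ``|sub|`` with an empty frame state, at
    ``target`` if given or at any graph position otherwise.
    """
    n = len(sub)
    C = sc.C
    goal_pos: set[tuple[str, int]] | None = None
    if target is not None:
        from .nt_align import _equivalent_positions

        goal_pos = {(p.edge, p.offset) for p in _equivalent_positions(g, target)}

    start_state = (start.edge, start.offset, 0, "")
    dist: dict[tuple, float] = {start_state: 0.0}
    pred: dict[tuple, tuple] = {}
    counter = itertools.count()
    heap: list = [(0.0, next(counter), start_state)]
    settled = 0
    cap = limits.cost_cap

    def relax(state, nstate, w, op, d):
        nd = d + w
        if cap is not None and nd > cap:
            return
        if nd < dist.get(nstate, float("inf")):
            dist[nstate] = nd
            pred[nstate] = (state, op)
            heapq.heappush(heap, (nd, next(counter), nstate))

    while heap:
        d, _, state = heapq.heappop(heap)
        if d > dist.get(state, float("inf")):
            continue
        eid, i, j, fs = state
        if j == n and fs == "" and (goal_pos is None or (eid, i) in goal_pos):
            return d, state, pred
        settled += 1
        if settled > limits.max_states:
            raise SearchLimitExceeded(f"state budget {limits.max_states} exhausted")
        label = g.edges[eid]
        elen = len(label)
        if i == elen:
            for to, ovl in g.out_links[eid]:  # rule 5: free vertex crossing
                relax(state, (to, ovl, j, fs), 0.0, "C", d)
        else:
            c = label[i]
            if len(fs) < 2:  # rule 1: accumulate a base
                relax(state, (eid, i + 1, j, fs + c), 0.0, "b", d)
            else:
                aa_g = _codon_aa(transform(fs + c))
                if j < n and aa_g != "*":  # rule 3: consume a residue
                    w = C + sc.cost(aa_g, sub[j])
                    op = "=" if aa_g == sub[j] else "X"
                    relax(state, (eid, i + 1, j + 1, ""), w, op, d)
                if aa_g != "*" or allow_deleted_stops:  # rule 2: delete codon
                    relax(state, (eid, i + 1, j, ""), sc.sigma, "D", d)
        if fs == "" and j < n:  # rule 4: insertion, only between codons
            relax(state, (eid, i, j + 1, ""), C + sc.sigma, "I", d)
    raise AlignmentNotFound("no AA-path within limits")


def _aa_traceback(start: GraphPosition, end_state, pred) -> tuple[GraphPath, str]:
    ops_rev: list[str] = []
    edges_rev = [end_state[0]]
    state = end_state
    start_state = (start.edge, start.offset, 0, "")
    while state != start_state:
        prev, op = pred[state]
        if op == "C":
            edges_rev.append(prev[0])
        elif op != "b":
            ops_rev.append(op)
        state = prev
    edges = list(reversed(edges_rev))
    path = GraphPath(
        edges,
        GraphPosition(edges[0], start.offset),
        GraphPosition(edges[-1], end_state[1]),
    )
    return path, "".join(reversed(ops_rev))


def _aa_result(
    path: GraphPath, ops: str, shifted: float, n_res: int, sc: AAScoringScheme
) -> AAPathResult:
    nt_consumed = 3 * sum(1 for o in ops if o in "=XD")
    return AAPathResult(
        path=path,
        ops=ops,
        weight=shifted - sc.C * n_res,
        shifted_weight=shifted,
        nt_consumed=nt_consumed,
    )


def extend_aa(
    g: AssemblyGraph,
    sub_p: str,
    start: GraphPosition,
    sc: AAScoringScheme | None = None,
    limits: SearchLimits | None = None,
    direction: str = "right",
    allow_deleted_stops: bool = False,
) -> AAPathResult:
    """Minimum-weight AA-path consuming ``sub_p`` from ``start`` onward.

    ``start`` must lie on a codon boundary of the intended frame.  With
    ``direction='left'`` the fragment is consumed leftward (pass it already
    reversed); codons are then completed as suffixes, realized by running
    the forward engine on the reverse-complement graph and reverse
    complementing each completed triple before translation.
    """
    sc = sc or AAScoringScheme()
    limits = limits or SearchLimits()
    if direction == "left":
        cost, end_state, pred = _aa_search(
            g, sub_p, g.rc_position(start), None, sc, limits, revcomp,
            allow_deleted_stops,
        )
        path, ops = _aa_traceback(g.rc_position(start), end_state, pred)
        res = _aa_result(g.rc_path(path), ops[::-1], cost, len(sub_p), sc)
        return res
    cost, end_state, pred = _aa_search(
        g, sub_p, start, None, sc, limits, lambda x: x, allow_deleted_stops
    )
    path, ops = _aa_traceback(start, end_state, pred)
    return _aa_result(path, ops, cost, len(sub_p), sc)


def aa_align_between(
    g: AssemblyGraph,
    sub_p: str,
    start: GraphPosition,
    end: GraphPosition,
    sc: AAScoringScheme | None = None,
    limits: SearchLimits | None = None,
) -> AAPathResult:
    """Fixed-endpoint variant: optimal AA-path from ``start`` to ``end``."""
    sc = sc or AAScoringScheme()
    limits = limits or SearchLimits()
    cost, end_state, pred = _aa_search(
        g, sub_p, start, end, sc, limits, lambda x: x
    )
    path, ops = _aa_traceback(start, end_state, pred)
    return _aa_result(path, ops, cost, len(sub_p), sc)


# -- anchor search ---------------------------------------------------------


class AAIndex:
    """Exact amino-acid k-mer index over six-frame edge translations."""

    def __init__(self, g: AssemblyGraph, k_aa: int = 5, max_occ: int = 100):
        self.g = g
        self.k_aa = k_aa
        self.frames: dict[tuple[str, int], str] = {}
        self.index: dict[str, list[tuple[str, int, int]]] = {}
        for eid in sorted(g.edges):
            label = g.edges[eid]
            for frame in range(3):
                ncod = (len(label) - frame) // 3
                if ncod <= 0:
                    continue
                prot = translate(label[frame : frame + 3 * ncod])
                self.frames[(eid, frame)] = prot
                for i in range(len(prot) - k_aa + 1):
                    kmer = prot[i : i + k_aa]
                    if "*" in kmer or "X" in kmer:
                        continue
                    self.index.setdefault(kmer, []).append((eid, frame, i))
        self.index = {k: v for k, v in self.index.items() if len(v) <= max_occ}


def find_aa_anchors(
    g: AssemblyGraph,
    q: str,
    k_aa: int = 5,
    min_len_nt: int | None = None,
    sc: AAScoringScheme | None = None,
    xdrop: float = 25.0,
    index: AAIndex | None = None,
) -> list[Anchor]:
    """Gap-free local matches between a protein query and edge translations.

    Seeds are exact amino-acid k-mers against the six frame translations of
    the edge labels (three frames per oriented edge); each seed is extended
    without gaps under the substitution matrix with an X-drop rule, never
    across a stop codon, so every anchor is frame-consistent by
    construction.  Anchors shorter than ``min_len_nt`` nucleotides (default:
    the graph's de Bruijn k, with a floor of 15) are discarded.  Query
    ranges are in residues; edge ranges in nucleotides with
    ``frame = start_e % 3``.
    """
    if not q:
        raise ValueError("empty query")
    sc = sc or AAScoringScheme()
    if min_len_nt is None:
        min_len_nt = max(g.k or 0, 15)
    if index is None or index.k_aa != k_aa:
        index = AAIndex(g, k_aa)
    q = q.upper()
    qmers: dict[str, list[int]] = {}
    for i in range(len(q) - k_aa + 1):
        qmers.setdefault(q[i : i + k_aa], []).append(i)
    seen_regions: dict[tuple[str, int, int], list[tuple[int, int]]] = {}
    anchors: set[Anchor] = set()
    for kmer in sorted(qmers):
        for eid, frame, tpos in index.index.get(kmer, ()):
            prot = index.frames[(eid, frame)]
            for qpos in qmers[kmer]:
                diag = qpos - tpos
                covered = seen_regions.get((eid, frame, diag), [])
                if any(a <= qpos and qpos + k_aa <= b for a, b in covered):
                    continue
                qs, qe, ts, te = _xdrop_extend(q, prot, qpos, tpos, k_aa, sc, xdrop)
                seen_regions.setdefault((eid, frame, diag), []).append((qs, qe))
                if 3 * (qe - qs) < min_len_nt:
                    continue
                anchors.add(
                    Anchor(qs, qe, eid, frame + 3 * ts, frame + 3 * te, frame=frame)
                )
    return sorted(anchors, key=lambda a: (a.start_s, a.edge, a.start_e))


def _xdrop_extend(q, prot, qpos, tpos, k, sc, xdrop):
    """Ungapped X-drop extension of an exact seed, in residue space."""
    # leftward
    best = run = 0.0
    qs, ts = qpos, tpos
    bi, bt = qs, ts
    while qs > 0 and ts > 0 and prot[ts - 1] not in "*":
        run += sc.score(prot[ts - 1], q[qs - 1])
        qs -= 1
        ts -= 1
        if run > best:
            best, bi, bt = run, qs, ts
        elif best - run > xdrop:
            break
    qs, ts = bi, bt
    # rightward from the seed end
    best = run = 0.0
    qe, te = qpos + k, tpos + k
    bj, bu = qe, te
    while qe < len(q) and te < len(prot) and prot[te] not in "*":
        run += sc.score(prot[te], q[qe])
        qe += 1
        te += 1
        if run > best:
            best, bj, bu = run, qe, te
        elif best - run > xdrop:
            break
    return qs, bj, ts, bu


# -- protein pipeline ------------------------------------------------------


@dataclass
class AAParams:
    """Tunables of the protein pipeline (matrix BLOSUM90, sigma=5,
    coverage threshold 0.8 by default)."""

    k_aa: int = 5
    min_anchor_nt: int | None = None
    min_coverage: float = 0.8
    max_anchors: int = 16
    max_states: int = 5_000_000
    allow_deleted_stops: bool = False
    neighborhood_pad: int = 300  # bp beyond 3*|fragment| when carving subgraphs


@dataclass
class ProteinAlignmentResult:
    """One scored AA-path for a protein query (best first in pipeline output)."""

    path: GraphPath
    translated: str
    score: float
    coverage: float
    identity: float
    frame: int


def _make_rescorer(sc: AAScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sc.matrix
    aligner.open_gap_score = -sc.sigma
    aligner.extend_gap_score = -sc.sigma
    return aligner


def rescore_protein(q: str, translated: str, sc: AAScoringScheme) -> tuple[float, float]:
    """Global matrix score of the translated path against the query, and the
    residue identity (matches / alignment columns) of the best alignment."""
    aligner = _make_rescorer(sc)
    aln = aligner.align(q, translated)[0]
    matches = 0
    for (qb, qe), (tb, te) in zip(*aln.aligned):
        matches += sum(1 for x, y in zip(q[qb:qe], translated[tb:te]) if x == y)
    columns = aln.shape[1]
    return float(aln.score), matches / columns if columns else 0.0


def align_protein(
    g: AssemblyGraph,
    q: str,
    sc: AAScoringScheme | None = None,
    params: AAParams | None = None,
    index: AAIndex | None = None,
) -> list[ProteinAlignmentResult]:
    """Align a protein query against all AA-paths of the graph.

    Each surviving anchor is extended left and right by the frame-state
    search (no chaining); paths covering less than ``min_coverage`` of the
    query coding length are dropped, identical paths are deduplicated, and
    the remainder are translated and re-scored with a classical global
    protein aligner.  Results are sorted best-first by re-scored value.
    """
    sc = sc or AAScoringScheme()
    params = params or AAParams()
    q = q.upper()
    anchors = find_aa_anchors(
        g, q, k_aa=params.k_aa, min_len_nt=params.min_anchor_nt, sc=sc, index=index
    )
    anchors = sorted(anchors, key=lambda a: (-a.span, a.edge, a.start_s))
    anchors = anchors[: params.max_anchors]
    results: list[ProteinAlignmentResult] = []
    seen_paths: set = set()
    for a in anchors:
        try:
            combined = _extend_anchor(g, q, a, sc, params)
        except AlignmentNotFound:
            logger.debug("anchor on %s dropped: no stop-free extension", a.edge)
            continue
        path, label = combined
        if len(label) % 3:
            raise AssertionError("AA-path label length not divisible by 3")
        coverage = len(label) / (3 * len(q))
        if coverage < params.min_coverage:
            continue
        key = (tuple(path.edges), path.start, path.end)
        if key in seen_paths:
            continue
        seen_paths.add(key)
        translated = translate(label)
        if "*" in translated:
            raise AssertionError("stop codon escaped the AA-path constraint")
        score, identity = rescore_protein(q, translated, sc)
        results.append(
            ProteinAlignmentResult(
                path=path,
                translated=translated,
                score=score,
                coverage=coverage,
                identity=identity,
                frame=path.start.offset % 3,
            )
        )
    results.sort(key=lambda r: (-r.score, r.path.start))
    return results


def _extend_anchor(g, q, a: Anchor, sc, params) -> tuple[GraphPath, str]:
    limits = SearchLimits(max_states=params.max_states)
    left_frag = q[: a.start_s][::-1]
    right_frag = q[a.end_s :]
    start = GraphPosition(a.edge, a.start_e)
    end = GraphPosition(a.edge, a.end_e)
    lg = _carve(g, start, len(left_frag), params)
    left = extend_aa(lg, left_frag, start, sc, limits, "left",
                     params.allow_deleted_stops)
    rg = _carve(g, end, len(right_frag), params)
    right = extend_aa(rg, right_frag, end, sc, limits, "right",
                      params.allow_deleted_stops)
    edges = left.path.edges[:-1] + [a.edge] + right.path.edges[1:]
    path = GraphPath(edges, left.path.start, right.path.end)
    label = label_of_path(g, path)
    return path, label


def _carve(g, pos, n_residues, params) -> AssemblyGraph:
    radius = 3 * n_residues + params.neighborhood_pad
    return extract_neighborhood(g, [pos], radius)
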