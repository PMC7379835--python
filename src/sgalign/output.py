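"""Tabular and GAF output for alignment results."""

from __future__ import annotations

from .aa_align import ProteinAlignmentResult
from .graph import AssemblyGraph, GraphPath, path_length
from .nt_align import AlignmentResult

NT_TSV_HEADER = (
    "name\tqstart\tqend\tqlen\tstart\tend\tpath\tpath_len\tidentity\tcigar"
)
AA_TSV_HEADER = (
    "name\tscore\tcoverage\tidentity\tpath\tpath_len\tframe\ttranslated"
)


def nt_tsv_row(name: str, qlen: int, r: AlignmentResult, g: AssemblyGraph) -> str:
    p = r.path
    return "\t".join(
        [
            name,
            str(r.query_range[0]),
            str(r.query_range[1]),
            str(qlen),
            f"{p.start.edge}:{p.start.offset}",
            f"{p.end.edge}:{p.end.offset}",
            ",".join(p.edges),
            str(path_length(g, p)),
            f"{r.identity:.4f}",
            r.cigar,
        ]
    )


def aa_tsv_row(name: str, r: ProteinAlignmentResult, g: AssemblyGraph) -> str:
    return "\t".join(
        [
            name,
            f"{r.score:.1f}",
            f"{r.coverage:.4f}",
            f"{r.identity:.4f}",
            ",".join(r.path.edges),
            str(path_length(g, r.path)),
            str(r.frame),
            r.translated,
        ]
    )


def _gaf_path(path: GraphPath) -> str:
    return "".join(
        (">" if e.endswith("+") else "<") + e[:-1] for e in path.edges
    )


def gaf_record(name: str, qlen: int, r: AlignmentResult, g: AssemblyGraph) -> str:
    """One GAF line (standard columns; the path as oriented segment names)."""
    p = r.path
    total = g.length(p.edges[0])
    for prev, cur in zip(p.edges, p.edges[1:]):
        total += g.length(cur) - g.overlap(prev, cur)
    pstart = p.start.offset
    pend = total - (g.length(p.edges[-1]) - p.end.offset)
    matches = r.ops.count("=")
    cols = len(r.ops)
    return "\t".join(
        [
            name,
            str(qlen),
            str(r.query_range[0]),
            str(r.query_range[1]),
            "+",
            _gaf_path(p),
            str(total),
            str(pstart),
            str(pend),
            str(matches),
            str(cols),
            "60",
            f"cg:Z:{r.cigar}",
        ]
    )
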