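"""GFA round trip, path labels, and the anchor machinery step by step.

Writes a toy graph to GFA, reads it back, then walks a query through the
individual pipeline stages: k-mer anchoring, the three filter rules, and
heaviest-chain selection.
"""

import tempfile

from sgalign import (
    AssemblyGraph, GraphPath, GraphPosition, filter_anchors, find_anchors,
    heaviest_chain, label_of_path, load_gfa, min_graph_distance, write_gfa,
)
from sgalign.simulate import SimulationConfig, build_compacted_dbg, simulate_genome

cfg = SimulationConfig(genome_length=25_000, repeat_count=1,
                       repeat_length=500, protein_count=0, seed=5)
genome, _ = simulate_genome(cfg)
graph, _ = build_compacted_dbg(genome, cfg.k)

with tempfile.NamedTemporaryFile("w", suffix=".gfa", delete=False) as fh:
    gfa_path = fh.name
write_gfa(graph, gfa_path)
graph = load_gfa(gfa_path)
print(f"GFA round trip: {len(graph.segment_names())} segments, k={graph.k}")

query = genome[2_000:20_000]  # long enough to cross a repeat copy
anchors = find_anchors(graph, query)
print(f"anchors found   : {len(anchors)} "
      f"(spans {min(a.span for a in anchors)}..{max(a.span for a in anchors)} bp)")
kept = filter_anchors(anchors, len(query), graph)  # t=200, T=500
print(f"after filtering : {len(kept)} (span >= 200 bp each)")
chain = heaviest_chain(graph, kept)  # alpha = 1.3
print(f"skeleton chain  : {len(chain.anchors)} anchors, "
      f"total weight {chain.total_weight:.0f} bp")
for a, b in zip(chain.anchors, chain.anchors[1:]):
    gap = b.start_s - a.end_s
    d = min_graph_distance(
        graph, GraphPosition(a.edge, a.end_e), GraphPosition(b.edge, b.start_e),
        cap=1.3 * gap,
    )
    print(f"  {a.edge} -> {b.edge}: query gap {gap} bp, graph distance {d:.0f} bp")

p = chain.anchors[0]
path = GraphPath([p.edge], GraphPosition(p.edge, p.start_e),
                 GraphPosition(p.edge, p.end_e))
assert label_of_path(graph, path) in genome  # anchors really match the genome
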