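# sgalign

Semi-global alignment of long, diverged nucleotide sequences **and protein
sequences** to assembly graphs (GFA 1.x), such as the compacted de Bruijn
graphs produced by SPAdes-family assemblers.

Assemblers increasingly hand users a graph, not just contigs: edges carry
nucleotide labels (unitigs) and vertices encode their potential adjacencies.
Mapping long error-prone reads (PacBio/ONT) onto that graph supports hybrid
assembly, read correction and haplotype analysis; mapping *protein* queries
onto it recovers genes — antibiotic-resistance genes in metagenomes are the
canonical case — that assembly fragmentation has scattered over several
contigs. `sgalign` is a library plus a small CLI for both tasks, aimed at
people who work with assembly graphs programmatically (Python) or from the
shell.

## The method

A query `S` is aligned semi-globally: we seek a graph path `P` minimizing the
linear-gap alignment cost between `Label(P)` (concatenated edge labels, link
overlaps trimmed) and `S`. The pipeline follows the anchor–chain–extend
paradigm:

1. **Anchor search** — local high-identity matches between `S` and individual
   edge labels (exact k-mer seeds, k=14, clustered per edge by diagonal and
   polished into gapped anchors with edlib). Anchors from an external mapper
   can be imported as PAF instead.
2. **Anchor filtering** — three ordered rules discard anchors that are (i)
   "in the middle" of long edges while spanning < T=500 bp, (ii) half-covered
   on the query by other anchors, (iii) shorter than t=200 bp.
3. **Anchor chaining** — the heaviest chain of *compatible* anchors
   (weight = span) by dynamic programming; anchors `a`, `b` are compatible
   when `dist_G(p_a, p_b) ≤ α·(start_S(b) − end_S(a))`, α = 1.3.
4. **Filling paths** — optimal paths between consecutive chain anchors (and
   beyond the terminal ones) are minimum-weight paths in the alignment graph
   `SG(G, Sub)`: vertices `⟨p, pos_Sub⟩`, edges for deletion (σ), insertion
   (σ), match/mismatch (0/μ), and free vertex crossings. Weights are
   non-negative, so Dijkstra applies; for edit distance (μ=σ=1, the default)
   a 0-1 BFS over a deque reaches the same optimum in O(|G|·|Sub|).

Protein queries use a frame-state alignment graph `SG_p`: states
`⟨p, pos, fs⟩` carry a 0–2 nt partial codon `fs`; completed codons are
scored against the query with `M′ = −M` (M = BLOSUM90 by default, gap
σ = 5 per codon/residue), and any completion that is a stop codon is
forbidden — every reported path is an *AA-path* whose translation is
stop-free. Because `M′` has negative entries, all query-consuming edges are
shifted by a constant `C > max(M)`; every source-to-sink path shifts by
exactly `|query|·C`, so Dijkstra on the shifted graph finds the true
optimum. Hits are then translated and re-scored with a classical global
protein aligner.

No external data is needed: `sgalign.simulate` generates random genomes with
planted repeats and ORFs, builds the compacted de Bruijn graph (with the
ground-truth path of every genome interval), and simulates error-prone reads
and mutated proteins, all from one seed.

## Worked example

```sh
python examples/align_protein_query.py
```

```
query: 181 residues, 11 substitutions vs truth
path      : u1+  (matches planted path: True)
score     : 1130  (BLOSUM90, sigma=5)
coverage  : 1.00 of the query coding length
identity  : 0.9392 amino-acid identity
```

The query is a planted 181-residue gene with 11 random substitutions
(~94% identity). The aligner finds the exact planted path, covers the whole
coding length, and reports the BLOSUM90 re-scored value; the identity is
matches over alignment columns of the best protein-level alignment.
`examples/align_long_reads.py` and `examples/graph_and_anchors.py` walk
through the nucleotide pipeline the same way.

From the shell:

```sh
sgalign simulate --out-dir fixture --seed 1 --error-rate 0.1
sgalign align --graph fixture/graph.gfa --queries fixture/reads.fastq \
    --out aln.tsv --gaf aln.gaf
sgalign align-protein --graph fixture/graph.gfa \
    --queries fixture/proteins.fasta --out prot.tsv
```

`align` prints a summary (`queries / mapped / mean_identity`), where a read
counts as mapped when one alignment path covers ≥ 80% of its length and
identity is measured on the longest continuous alignment.

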