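# Methods

## Graph model

An assembly graph is a directed, edge-labeled graph. Every GFA segment
yields two directed edges (`seg+`, `seg-`) with reverse-complement labels,
so reverse-strand queries need no special casing; `rc(rc(e)) = e` always
holds. Links carry an overlap (from the `<int>M` CIGAR; `*` is 0) that is
trimmed from the *successor's* prefix whenever labels are concatenated, and
the same trimming enters distance computations. Two validity rules are
enforced at load time because `Label(P)` is otherwise ill-defined: the
overlapping sequences of a link must actually agree (suffix of the
predecessor equals prefix of the successor), and only one link may exist
per oriented edge pair. De Bruijn assembler output satisfies both.

Coordinates are 0-based, half-open, and positions sit *between* characters:
`(e, i)` with `0 ≤ i ≤ |e|`. A position whose offset falls inside an
incoming link's overlap is physically identical to a position near the end
of the predecessor edge; the searches treat these representations as
interchangeable when matching endpoints.

`min_graph_distance` is a Dijkstra over edge-entry states with weight
`|e| − overlap` per hop; it is exact under overlap trimming (the first hop
may carry a negative offset correction, after which all weights are
positive) and terminates once the frontier exceeds the caller's cap.
`extract_neighborhood` keeps every edge whose first untrimmed character
lies within the radius, forward or backward of any seed, closed under
reverse complement; restricting a search to such a neighborhood is exact
whenever the optimal path fits inside the radius.

## Nucleotide pipeline

**Seeding.** Exact k-mer seeds (k_seed = 14 by default) against an index of
all oriented edge labels, clustered per edge by query order and bounded
diagonal drift (30% of the query gap plus 30 bp — generous for long-read
indel rates), then polished into one gapped anchor per cluster by a global
edlib alignment between the cluster's query and edge ranges. Cluster
endpoints are exact seed matches, so the global alignment is anchored;
clusters above 35% divergence are dropped. Anchors below the graph's
de Bruijn k (or k_seed if unknown) are discarded at discovery. An ungapped
seeder cannot replace this: with ~10% errors including indels, exact runs
average ~10 bp and no ungapped extension reaches the 200 bp the filter
demands — gapped polish is what makes long anchors exist. Hyper-repetitive
seeds (> 200 occurrences) are skipped. Externally computed anchors can be
read from PAF (minus-strand records are flipped onto the rc edge) and flow
through the identical filter.

**Filtering** applies three rules in order: (1) anchors "in the middle" of
long edges — `span_e + min(start_S, start_e) + min(|S|−end_S, |e|−end_e) >
3·span_e` — spanning less than T = 500 bp; (2) anchors at least half of
whose query range is covered by other anchors; (3) anchors spanning less
than t = 200 bp. Rule 2 is realized as a greedy sweep in priority order
(largest span, then smallest edge id, then query start): an anchor is kept
when the already-kept set covers less than half of its range. This keeps
exactly one representative of a mutually-covering set — dropping *all*
members, which a literal reading of the rule would do for symmetric pairs,
costs sensitivity for nothing — and makes the filter idempotent.

**Chaining.** Weights equal spans. `b` is compatible after `a` when it
follows without query overlap and the minimal graph distance between the
facing endpoints is at most α (default 1.3) times the query gap; a zero
query gap requires zero graph distance. Distance queries are capped at
α·gap, which suffices to decide the predicate. The O(n²) DP breaks ties by
smaller accumulated graph distance, then by lexicographically smallest
index sequence, so results are deterministic.

**Filling and extension.** Between consecutive skeleton anchors the
fragment `Sub = S[end_S(a) : start_S(b)]` is aligned by shortest path in
the implicit alignment graph: deletion and insertion edges cost σ, diagonal
edges 0 or μ, vertex crossings 0; `N` in a label never matches. Defaults
are μ = σ = 1 (edit distance), where a 0-1 BFS over a deque replaces the
heap. Each subtask runs on the neighborhood of its endpoints with radius
α·|Sub| + 2t and a cost cap of σ·(1+α)·|Sub| plus slack — a true upper
bound for chain-compatible endpoints (delete the whole connecting path,
insert the whole fragment), not a heuristic cut. Terminal fragments extend
from the outermost anchors to any graph position consuming the whole
fragment; left extension runs the forward engine on the reverse-complement
graph with the reverse-complemented fragment. Terminal extensions are
abandoned when their cost exceeds 35% of σ·|fragment| (tails more diverged
than that are better reported unaligned); a failed middle fill cuts the
chain and keeps the heavier side; either degradation only reduces reported
query coverage. The per-subtask state budget is 5·10⁶ settled states.

Anchor interiors are re-transcribed (edlib) during assembly, so the final
CIGAR (`= X I D`, query-centric) replays exactly: replaying it against
`Label(path)` and the query reproduces the reported cost — a tested
invariant. Equal-cost predecessors prefer diagonal over deletion over
insertion, making CIGARs deterministic. Identity is matches over alignment
columns; a query is *mapped* when one path covers at least 80% of it.

## Protein pipeline

**Frame-state search.** States `⟨p, j, fs⟩` extend the nucleotide states
with a partial codon `fs` (|fs| ≤ 2, 21 possible values). Rules: (1)
accumulate a base, free; (2) delete a completed codon, σ (per codon — the
rule fires once per completed triple); (3) consume a query residue against
a completed codon at cost `−M[aa_g, aa_q]`; (4) insert a query residue,
σ, only at `fs = ε`, so gaps are codon-aligned on the graph side; (5)
cross a vertex, free — codons may span edges. Completions that translate
to a stop are forbidden for both rules 2 and 3, which is precisely the
AA-path constraint; a flag can re-admit *deleted* stop codons for
pseudo-gene hunting (off by default). Since `−M` has negative entries,
rules 3 and 4 are shifted by `C = max(M) + 1`; any `C > max(M)` gives the
same optima because every source-to-sink path contains exactly `|query|`
shifted edges (tested for three choices of C). The search terminates at
query position `|Sub_p|` with `fs = ε` — the terminus consistent with that
counting argument. Left extension reverse-complements each completed
triple before translation (codons built as suffixes on the rc graph) and
consumes the reversed fragment.

**Anchors.** Seeds are exact amino-acid 5-mers between the query and the
six frame translations of the edge labels (three frames per oriented
edge), extended without gaps under the substitution matrix with an X-drop
of 25, never across a stop: frame-consistent and gap-free by construction.
Anchors shorter than the graph k in nucleotides (floor 15 nt = 5 codons)
are dropped. Proteins are short enough that chaining is unnecessary — each
anchor is extended independently, which also avoids coordinating reading
frames across anchors. Seeding in residue space rather than on
"canonical-codon" nucleotide encodings is deliberate: exact nucleotide
seeds on a minimal-codon encoding almost never occur when the target gene
uses arbitrary synonymous codons, whereas residue seeds depend only on
amino-acid identity.

**Post-processing.** Per anchor (the 16 widest after deduplication by
frame/diagonal) the query is extended left and right; paths shorter than
0.8 of the query coding length (3·|query| nt) are dropped; identical paths
are deduplicated; survivors are translated and re-scored with a global
protein aligner (same matrix, linear gap σ = 5) — the reported score and
identity come from that re-scoring. Results are sorted best-first.

## Synthetic data

The generator emulates the aligner's target setting at desk scale: a
random genome (default 100 kb) with planted exact repeats (4 × 400 bp —
long enough to collapse into branch edges, shorter than the reads so flank
anchors exist) and planted ORFs (20 genes of 100–300 codons: ATG, random
sense codons, one stop); a node-centric compacted de Bruijn graph over
both strands (k = 21, unitig ids assigned in lexicographic order of
canonical labels, links overlap k−1); reads of 2–5 kb from either strand
through a per-base error channel (the "10%" condition is 5% mismatch,
2.5% insertion, 2.5% deletion — a long-read-like mix); and protein queries
mutated by residue substitution (rate 0.1 ≈ 90% identity). Everything is
reproducible from one seed, byte-identical on disk.

What it does *not* model: homopolymer-biased ONT errors, coverage-dependent
assembly artifacts (tips, bubbles from sequencing error), diverged repeat
families, codon usage bias, or genes split across strand switches. Passing
round-trip tests therefore demonstrates correctness of the alignment
machinery on realistic graph topologies and error rates, not performance
parity with production aligners on real sequencing data.

Test and acceptance problem sizes — 100 kb genomes, 200 reads per
condition, 20 genes, and a few hundred randomized oracle instances per
equivalence property — were chosen so the whole suite completes in well
under a minute of alignment work while still exercising multi-unitig
paths, repeat crossings and both strands.

## Numerical and degenerate-input choices

* Match cost is 0; μ ≥ 0, σ > 0. Costs are exact floats (small integers in
  practice); no rounding is involved.
* Empty fragments between coincident positions yield empty paths of cost
  0; an empty query file is a valid run; a query with no surviving anchors
  is reported unaligned rather than erroring.
* Unreachable targets raise a distinct "no path" failure; exhausted state
  budgets raise a "limit exceeded" failure; the pipeline degrades to
  partial alignments on either.
* `N` never matches (mismatch cost applies); codons containing `N`
  translate to `X`, which scores as the matrix's `X` column.
* All tie-breaks (anchor order, chain choice, predecessor preference,
  segment ids) are lexicographic and documented above, so identical inputs
  and seeds give identical outputs, including across process restarts.

## Known limitations

* Linear gap penalties only; affine gaps would need a gap-state extension
  of the alignment graph.
* No split-read output: one best semi-global alignment per query.
* No frameshift tolerance in protein mode (single-base indels inside
  codons break the frame by design).
* The O(n²) chain DP and pure-Python search loops are comfortable at
  assembly-graph scale for thousands of queries, but this implementation
  optimizes clarity and testability over raw throughput.
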