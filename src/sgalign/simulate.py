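"""Deterministic synthetic data: genomes, compacted de Bruijn graphs,
error-prone long reads and mutated proteins.

The generator emulates, at desk scale, the setting the aligner is built
for: a short-read assembly graph (here a compacted de Bruijn graph built
directly from a simulated genome) plus long error-prone reads and diverged
protein queries.  Planted repeats create the branching structure that makes
graph alignment non-trivial; planted ORFs give protein queries a known
ground-truth path.  Everything is driven by one integer seed and is
byte-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .aa_align import CODON_TABLE
from .graph import AssemblyGraph, GraphPath, GraphPosition, revcomp

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODONS_OF: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    if _aa != "*":
        _CODONS_OF.setdefault(_aa, []).append(_codon)


@dataclass
class PlantedORF:
    """Ground truth for one planted gene: genome interval of the coding
    sequence (start codon through last sense codon, stop excluded)."""

    start: int
    end: int
    strand: str
    protein: str


@dataclass
class PlantedRepeat:
    source: tuple[int, int]
    copy: tuple[int, int]
    identity: float


@dataclass
class SimulationConfig:
    genome_length: int = 100_000
    repeat_count: int = 4
    repeat_length: int = 400
    repeat_identity: float = 1.0
    read_count: int = 200
    read_length: tuple[int, int] = (2000, 5000)
    mismatch_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    protein_count: int = 20
    protein_length: tuple[int, int] = (100, 300)  # codons
    protein_mutation_rate: float = 0.1
    k: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.mismatch_rate, self.ins_rate, self.del_rate,
                  self.protein_mutation_rate, self.repeat_identity):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.k % 2 == 0 or not 11 <= self.k <= 77:
            raise ValueError("k must be odd and in [11, 77]")

    def noisy(self, total: float = 0.1) -> "SimulationConfig":
        """The same conditions with a PacBio-like error mix summing to
        ``total``: half mismatches, a quarter insertions, a quarter
        deletions."""
        return replace(
            self,
            mismatch_rate=total / 2,
            ins_rate=total / 4,
            del_rate=total / 4,
        )


@dataclass
class Annotations:
    orfs: list[PlantedORF] = field(default_factory=list)
    repeats: list[PlantedRepeat] = field(default_factory=list)


def simulate_genome(cfg: SimulationConfig) -> tuple[str, Annotations]:
    """Random genome with planted repeats and planted ORFs.

    Repeats are planted first (a copied segment, optionally diverged), then
    ORFs into regions free of other plants; annotations carry the true
    coordinates.
    """
    if cfg.genome_length < 10 * cfg.k:
        raise ValueError("genome too short for the chosen k")
    if cfg.repeat_count and cfg.repeat_length >= cfg.genome_length // 2:
        raise ValueError("repeat longer than half the genome")
    rng = random.Random(cfg.seed)
    genome = [rng.choice(_BASES) for _ in range(cfg.genome_length)]
    ann = Annotations()
    occupied: list[tuple[int, int]] = []

    def place(length: int) -> int | None:
        for _ in range(200):
            start = rng.randrange(0, cfg.genome_length - length)
            if all(e <= start or s >= start + length for s, e in occupied):
                occupied.append((start, start + length))
                return start
        return None

    for _ in range(cfg.repeat_count):
        src = place(cfg.repeat_length)
        dst = place(cfg.repeat_length)
        if src is None or dst is None:
            break
        seg = genome[src : src + cfg.repeat_length]
        seg = [
            b if rng.random() < cfg.repeat_identity else rng.choice(_BASES.replace(b, ""))
            for b in seg
        ]
        genome[dst : dst + cfg.repeat_length] = seg
        ann.repeats.append(
            PlantedRepeat((src, src + cfg.repeat_length),
                          (dst, dst + cfg.repeat_length), cfg.repeat_identity)
        )

    for _ in range(cfg.protein_count):
        ncod = rng.randint(*cfg.protein_length)
        nt_len = 3 * (ncod + 1)  # coding + stop
        start = place(nt_len)
        if start is None:
            break
        protein = "M" + "".join(rng.choice(_AA20) for _ in range(ncod - 1))
        coding = "".join(rng.choice(_CODONS_OF[a]) for a in protein)
        orf_nt = coding + rng.choice(_STOPS)
        genome[start : start + nt_len] = list(orf_nt)
        ann.orfs.append(PlantedORF(start, start + 3 * ncod, "+", protein))

    return "".join(genome), ann


# -- compacted de Bruijn graph --------------------------------------------


class GenomeGraphMap:
    """Maps genome intervals to their unique graph path (ground truth)."""

    def __init__(self, k: int, kmer_to_pos: dict[str, tuple[str, int]]):
        self.k = k
        self._map = kmer_to_pos

    def path_for_interval(self, genome: str, a: int, b: int) -> GraphPath:
        """The graph path spelling ``genome[a:b]`` (requires ``b - a >= k``)."""
        k = self.k
        if b - a < k:
            raise ValueError(f"interval shorter than k={k}")
        e0, o0 = self._map[genome[a : a + k]]
        edges = [e0]
        cur_e, cur_o = e0, o0
        for i in range(a + 1, b - k + 1):
            e, o = self._map[genome[i : i + k]]
            if e == cur_e and o == cur_o + 1:
                cur_e, cur_o = e, o
                continue
            if o != 0:
                raise AssertionError("discontinuous ground-truth walk")
            edges.append(e)
            cur_e, cur_o = e, o
        return GraphPath(
            edges, GraphPosition(e0, o0), GraphPosition(cur_e, cur_o + k)
        )


def build_compacted_dbg(
    genomes: str | list[str], k: int
) -> tuple[AssemblyGraph, GenomeGraphMap]:
    """Compacted de Bruijn graph over both strands of the input genome(s).

    Unitigs (maximal non-branching k-mer paths) become edges; adjacent
    unitigs overlap by k-1 bp.  Segment ids are assigned in lexicographic
    order of canonical labels, so the construction is deterministic.  Also
    returns the genome-to-graph map used as ground truth by the read and
    gene simulators.
    """
    if isinstance(genomes, str):
        genomes = [genomes]
    if k % 2 == 0 or not 11 <= k <= 77:
        raise ValueError("k must be odd and in [11, 77]")
    kmers: set[str] = set()
    for gseq in genomes:
        for strand in (gseq, revcomp(gseq)):
            for i in range(len(strand) - k + 1):
                kmers.add(strand[i : i + k])

    def outs(node: str) -> list[str]:
        return [node + c for c in _BASES if node + c in kmers]

    def ins(node: str) -> list[str]:
        return [c + node for c in _BASES if c + node in kmers]

    def branching(node: str) -> bool:
        return len(outs(node)) != 1 or len(ins(node)) != 1

    assigned: dict[str, tuple[int, int]] = {}  # kmer -> (walk id, index)
    walks: list[list[str]] = []

    def walk_from(start: str) -> None:
        chain = [start]
        assigned[start] = (len(walks), 0)
        cur = start
        while True:
            node = cur[1:]
            if branching(node):
                break
            nxt = outs(node)[0]
            if nxt in assigned:
                break
            assigned[nxt] = (len(walks), len(chain))
            chain.append(nxt)
            cur = nxt
        walks.append(chain)

    for x in sorted(kmers):
        if x not in assigned and branching(x[:-1]):
            walk_from(x)
    for x in sorted(kmers):  # leftovers live on perfect cycles
        if x not in assigned:
            walk_from(x)

    labels = [w[0] + "".join(x[-1] for x in w[1:]) for w in walks]
    canon = [min(lab, revcomp(lab)) for lab in labels]
    seg_of_canon: dict[str, str] = {}
    for c in sorted(set(canon)):
        seg_of_canon[c] = f"u{len(seg_of_canon) + 1}"

    g = AssemblyGraph(k=k)
    for c, name in seg_of_canon.items():
        g.add_segment(name, c)

    walk_edge: list[str] = []
    for lab, c in zip(labels, canon):
        walk_edge.append(seg_of_canon[c] + ("+" if lab == c else "-"))

    kmer_to_pos = {
        kmer: (walk_edge[wid], idx) for kmer, (wid, idx) in assigned.items()
    }

    links: set[tuple[str, str]] = set()
    for wid, w in enumerate(walks):
        node = w[-1][1:]
        for nxt in outs(node):
            nwid, nidx = assigned[nxt]
            if nidx != 0:
                continue  # continuation inside a unitig, not a junction
            links.add((walk_edge[wid], walk_edge[nwid]))
    for a, b in sorted(links):
        g.add_link(a, b, k - 1)

    return g, GenomeGraphMap(k, kmer_to_pos)


# -- reads and proteins ----------------------------------------------------


@dataclass
class SimulatedRead:
    name: str
    seq: str
    strand: str
    start: int
    end: int  # genome interval of the error-free template


def simulate_reads(genome: str, cfg: SimulationConfig) -> list[SimulatedRead]:
    """Reads drawn from either strand with a per-base error channel.

    Each template base independently mutates (substitution), gains a random
    inserted base after it, or is deleted, at the configured rates; the
    ground-truth genome interval and strand are retained.
    """
    rng = random.Random(cfg.seed + 1)
    reads = []
    lmin, lmax = cfg.read_length
    for idx in range(cfg.read_count):
        length = rng.randint(lmin, min(lmax, len(genome)))
        start = rng.randrange(0, len(genome) - length + 1)
        template = genome[start : start + length]
        strand = rng.choice("+-")
        if strand == "-":
            template = revcomp(template)
        seq = _apply_errors(template, cfg, rng)
        reads.append(
            SimulatedRead(f"read{idx + 1}", seq, strand, start, start + length)
        )
    return reads


def _apply_errors(template: str, cfg: SimulationConfig, rng: random.Random) -> str:
    out = []
    p_mis, p_ins, p_del = cfg.mismatch_rate, cfg.ins_rate, cfg.del_rate
    for b in template:
        r = rng.random()
        if r < p_mis:
            out.append(rng.choice(_BASES.replace(b, "")))
        elif r < p_mis + p_ins:
            out.append(b)
            out.append(rng.choice(_BASES))
        elif r < p_mis + p_ins + p_del:
            continue
        else:
            out.append(b)
    return "".join(out)


def mutate_protein(p: str, rate: float, seed: int) -> str:
    """Substitute residues at the given per-residue rate (length preserved)."""
    rng = random.Random(seed)
    out = []
    for a in p:
        if rng.random() < rate:
            out.append(rng.choice(_AA20.replace(a, "") if a in _AA20 else _AA20))
        else:
            out.append(a)
    return "".join(out)


# -- on-disk bundles -------------------------------------------------------


def write_fixture_bundle(cfg: SimulationConfig, out_dir: str) -> dict[str, str]:
    """Write GFA + reads + proteins + truth TSV; byte-identical per seed."""
    import os

    from .graph import write_gfa

    os.makedirs(out_dir, exist_ok=True)
    genome, ann = simulate_genome(cfg)
    g, gmap = build_compacted_dbg(genome, cfg.k)
    reads = simulate_reads(genome, cfg)
    paths = {
        "gfa": os.path.join(out_dir, "graph.gfa"),
        "reads": os.path.join(out_dir, "reads.fastq"),
        "proteins": os.path.join(out_dir, "proteins.fasta"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "genome": os.path.join(out_dir, "genome.fasta"),
    }
    write_gfa(g, paths["gfa"])
    with open(paths["genome"], "w") as fh:
        fh.write(">genome\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i : i + 80] + "\n")
    with open(paths["reads"], "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
    with open(paths["proteins"], "w") as fh:
        for i, orf in enumerate(ann.orfs):
            q = mutate_protein(orf.protein, cfg.protein_mutation_rate,
                               cfg.seed + 1000 + i)
            fh.write(f">prot{i + 1}\n{q}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("name\ttype\tstrand\tstart\tend\tpath\n")
        for r in reads:
            p = gmap.path_for_interval(genome, r.start, r.end)
            fh.write(
                f"{r.name}\tread\t{r.strand}\t{r.start}\t{r.end}\t"
                f"{','.join(p.edges)}\n"
            )
        for i, orf in enumerate(ann.orfs):
            p = gmap.path_for_interval(genome, orf.start, orf.end)
            fh.write(
                f"prot{i + 1}\torf\t{orf.strand}\t{orf.start}\t{orf.end}\t"
                f"{','.join(p.edges)}\n"
            )
    return paths
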