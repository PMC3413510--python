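"""Contig-connection graph: parsing, copy-number calls, filtering, export.

The on-disk dialect is TSV with '#' comments:

    C <id> <length> <depth>
    L <idA> <L|R> <idB> <L|R> <support>

A contig has two sides, L (5' of the stored strand) and R (3'); a connection
records which sides touch, so inverted joins are representable.  Connections
are undirected and duplicate unordered endpoint pairs merge with summed
support.  Copy number is called from read depth: the baseline is the
length-weighted median depth of contigs whose both ends have at most one
connection (the unambiguous backbone), and each contig's copy count is its
depth over that baseline, rounded, floor one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .seqio import FormatError


@dataclass
class Contig:
    id: str
    length: int
    depth: float
    residues: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.id}: length must be positive")
        if self.depth < 0:
            raise ValueError(f"contig {self.id}: negative depth")
        if self.residues is not None and len(self.residues) != self.length:
            raise ValueError(f"contig {self.id}: residues/length mismatch")


Endpoint = tuple[str, str]  # (contig id, side L/R)


@dataclass(frozen=True)
class Connection:
    a: Endpoint
    b: Endpoint
    support: int

    def key(self) -> frozenset:
        return frozenset([self.a, self.b]) if self.a != self.b else frozenset([self.a])


@dataclass
class ContigGraph:
    contigs: dict[str, Contig]
    connections: list[Connection]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: dict[frozenset, Connection] = {}
        for c in self.connections:
            if c.a[0] not in self.contigs or c.b[0] not in self.contigs:
                missing = c.a[0] if c.a[0] not in self.contigs else c.b[0]
                raise FormatError(f"connection references unknown contig {missing!r}")
            if c.support < 0:
                raise FormatError("negative connection support")
            k = c.key()
            if k in merged:
                merged[k] = replace(merged[k], support=merged[k].support + c.support)
            else:
                merged[k] = c
        self.connections = sorted(merged.values(), key=lambda c: sorted([c.a, c.b]))

    def end_degree(self, contig_id: str, side: str) -> int:
        ep = (contig_id, side)
        return sum((c.a == ep) + (c.b == ep) for c in self.connections)

    def neighbors(self, contig_id: str) -> set[str]:
        out = set()
        for c in self.connections:
            if c.a[0] == contig_id:
                out.add(c.b[0])
            if c.b[0] == contig_id:
                out.add(c.a[0])
        return out

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for cid in sorted(self.contigs):
            c = self.contigs[cid]
            g.add_node(cid, length=c.length, depth=c.depth, size=float(c.length))
        for c in self.connections:
            g.add_edge(c.a[0], c.b[0], sideA=c.a[1], sideB=c.b[1], support=c.support)
        return g


@dataclass(frozen=True)
class CopyNumberCall:
    contig_id: str
    copies: int
    depth_ratio: float

    @property
    def klass(self) -> str:
        return "repeat" if self.copies >= 2 else "single"


def parse_graph(path) -> ContigGraph:
    """Parse the canonical graph dialect (permissive about trailing columns)."""
    contigs: dict[str, Contig] = {}
    raw_connections: list[tuple] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            tag = parts[0]
            try:
                if tag == "C":
                    cid, length, depth = parts[1], int(parts[2]), float(parts[3])
                    if length <= 0 or depth < 0:
                        raise ValueError("negative field")
                    contigs[cid] = Contig(cid, length, depth)
                elif tag == "L":
                    cid_a, side_a, cid_b, side_b, support = parts[1:6]
                    if side_a not in "LR" or side_b not in "LR":
                        raise ValueError(f"bad side {side_a!r}/{side_b!r}")
                    if int(support) < 0:
                        raise ValueError("negative support")
                    raw_connections.append(((cid_a, side_a), (cid_b, side_b), int(support)))
                else:
                    raise ValueError(f"unknown record tag {tag!r}")
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    for ln_idx, (a, b, _s) in enumerate(raw_connections):
        for cid in (a[0], b[0]):
            if cid not in contigs:
                raise FormatError(f"{path}: connection references unknown contig {cid!r}")
    conns = [Connection(a, b, s) for a, b, s in raw_connections]
    return ContigGraph(contigs, conns, provenance=[f"parsed {path}"])


def classify_copy_number(graph: ContigGraph, min_support: int = 0) -> list[CopyNumberCall]:
    """Estimate per-contig copy number from depth ratios.

    Baseline = length-weighted median depth over contigs whose both ends have
    degree <= 1 (counting only connections with support >= ``min_support``);
    one refinement pass drops contigs the first pass called repeat from the
    baseline set.
    """
    if not graph.contigs:
        raise ValueError("empty graph")
    work = filter_connections(graph, min_support) if min_support > 0 else graph

    def baseline_over(candidate_ids: set[str]) -> float:
        cands = [work.contigs[c] for c in sorted(candidate_ids)
                 if work.end_degree(c, "L") <= 1 and work.end_degree(c, "R") <= 1]
        if not cands:
            raise ValueError(
                "no baseline candidates (every contig looks repeat-like); "
                "supply a baseline depth explicitly"
            )
        depths = np.array([c.depth for c in cands])
        weights = np.array([c.length for c in cands], dtype=float)
        order = np.argsort(depths)
        cum = np.cumsum(weights[order])
        idx = int(np.searchsorted(cum, cum[-1] / 2.0))
        return float(depths[order][idx])

    candidates = set(work.contigs)
    base = baseline_over(candidates)
    for _ in range(2):
        calls = []
        for cid in sorted(work.contigs):
            ratio = work.contigs[cid].depth / base
            copies = max(1, int(round(ratio)))
            calls.append(CopyNumberCall(cid, copies, ratio))
        repeat_ids = {c.contig_id for c in calls if c.copies >= 2}
        remaining = candidates - repeat_ids
        try:
            new_base = baseline_over(remaining)
        except ValueError:
            break
        if new_base == base:
            break
        base = new_base
    return calls


def classify_with_baseline(graph: ContigGraph, baseline_depth: float) -> list[CopyNumberCall]:
    """Copy-number calls against a user-supplied baseline depth."""
    if baseline_depth <= 0:
        raise ValueError("baseline depth must be positive")
    return [CopyNumberCall(cid, max(1, int(round(graph.contigs[cid].depth / baseline_depth))),
                           graph.contigs[cid].depth / baseline_depth)
            for cid in sorted(graph.contigs)]


def filter_connections(graph: ContigGraph, min_support: int) -> ContigGraph:
    """Drop connections with support below the threshold."""
    if min_support < 0:
        raise ValueError("min support must be >= 0")
    kept = [c for c in graph.connections if c.support >= min_support]
    return ContigGraph(dict(graph.contigs), kept,
                       graph.provenance + [f"filtered min_support={min_support}"])


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def seed_component(graph: ContigGraph, seed_sequence: str, k: int = 17) -> ContigGraph:
    """Return the connected component containing the contig most similar to a seed.

    Similarity is shared k-mer count (either strand of the seed).  A tie for
    the best contig or a seed sharing no k-mer with any contig is an error.
    """
    from .seqio import revcomp

    if not seed_sequence:
        raise ValueError("empty seed sequence")
    seed_k = _kmers(seed_sequence.upper(), k) | _kmers(revcomp(seed_sequence.upper()), k)
    scores = {}
    for cid in sorted(graph.contigs):
        res = graph.contigs[cid].residues
        if res is None:
            raise ValueError(f"contig {cid} has no residues loaded")
        scores[cid] = len(_kmers(res, k) & seed_k)
    best = max(scores.values(), default=0)
    if best == 0:
        raise ValueError("seed shares no k-mer with any contig")
    winners = sorted(c for c, s in scores.items() if s == best)
    if len(winners) > 1:
        raise ValueError(f"seed matches several contigs equally well: {winners}")
    g = graph.to_networkx()
    component = nx.node_connected_component(g, winners[0])
    contigs = {cid: graph.contigs[cid] for cid in component}
    conns = [c for c in graph.connections
             if c.a[0] in component and c.b[0] in component]
    return ContigGraph(contigs, conns,
                       graph.provenance + [f"seeded component at {winners[0]}"])


def export_network(graph: ContigGraph, path, fmt: str = "graphml") -> None:
    """Write the graph as GraphML or DOT with deterministic node ordering."""
    g = graph.to_networkx()
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True, edge_id_from_attribute=None)
    elif fmt == "dot":
        lines = ["graph contigs {"]
        for node in sorted(g.nodes):
            d = g.nodes[node]
            lines.append(
                f'  "{node}" [length={d["length"]}, depth={d["depth"]:.2f}, '
                f'width={d["size"] / 1000.0:.3f}];'
            )
        for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1], e[2]["support"])):
            lines.append(
                f'  "{u}" -- "{v}" [label={d["support"]}, sideA="{d["sideA"]}", '
                f'sideB="{d["sideB"]}"];'
            )
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def load_residues(graph: ContigGraph, records) -> None:
    """Attach FASTA residues to contigs in place (ids must match)."""
    by_id = {r.id: r.residues for r in records}
    for cid, contig in graph.contigs.items():
        if cid in by_id:
            seq = by_id[cid]
            if len(seq) != contig.length:
                raise FormatError(
                    f"contig {cid}: FASTA length {len(seq)} != declared {contig.length}"
                )
            contig.residues = seq
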