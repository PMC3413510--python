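"""Master-circle enumeration and sub-circle construction.

A master circle is a closed walk over the contig graph that uses every contig
exactly its called copy-count times, with every step supported by a recorded
connection whose sides are compatible with the traversal orientations
(traversing '+' enters at side L and exits at R; '-' the reverse).  Plant
mitochondrial graphs are small, so enumeration is exhaustive backtracking with
a solution cap; solutions are deduplicated under rotation and reflection.

Recombination across a direct repeat pair splits the master circle into two
sub-circles, each carrying one repeat copy; an inverted pair instead yields an
inversion isomer (a different master circle), which this module reports as an
error rather than a fission product.
"""

from __future__ import annotations

from dataclasses import dataclass

from .contigraph import ContigGraph, CopyNumberCall
from .seqio import GenomeSequence, SequenceRecord, revcomp

Step = tuple[str, str]  # (contig id, orientation + / -)


@dataclass
class CircleWalk:
    steps: tuple[Step, ...]
    closed: bool = True

    def __len__(self) -> int:
        return len(self.steps)

    def canonical(self) -> tuple[Step, ...]:
        """Rotation- and reflection-invariant representative of the cyclic walk."""
        def rotations(steps):
            n = len(steps)
            return [tuple(steps[i:] + steps[:i]) for i in range(n)]

        flipped = [(cid, "-" if o == "+" else "+") for cid, o in reversed(self.steps)]
        cands = rotations(list(self.steps)) + rotations(flipped)
        return min(cands)


class AssemblyGapError(RuntimeError):
    """No closed walk exists; carries a diagnostic of unsatisfiable ends."""


def _exit_side(orient: str) -> str:
    return "R" if orient == "+" else "L"


def _entry_orientation(side: str) -> str:
    return "+" if side == "L" else "-"


def _transitions(graph: ContigGraph) -> dict[Step, list[Step]]:
    """For each (contig, orientation) the steps reachable through a connection."""
    out: dict[Step, list[Step]] = {}
    for conn in graph.connections:
        for (ep_from, ep_to) in ((conn.a, conn.b), (conn.b, conn.a)):
            cid, side = ep_from
            # arriving at ep_from means we exited cid at `side`
            orient_from = "+" if side == "R" else "-"
            nxt = (ep_to[0], _entry_orientation(ep_to[1]))
            out.setdefault((cid, orient_from), []).append(nxt)
    for k in out:
        out[k] = sorted(set(out[k]))
    return out


def enumerate_master_circles(graph: ContigGraph,
                             calls: list[CopyNumberCall] | dict[str, int],
                             max_solutions: int = 64) -> list[CircleWalk]:
    """All closed walks using each contig its copy-count times, deduplicated.

    Returns walks in canonical order.  Raises AssemblyGapError when no closed
    walk exists, listing contig ends with no usable connection.
    """
    if isinstance(calls, dict):
        copies = dict(calls)
    else:
        copies = {c.contig_id: c.copies for c in calls}
    for cid in graph.contigs:
        copies.setdefault(cid, 1)

    trans = _transitions(graph)
    total_steps = sum(copies[cid] for cid in graph.contigs)
    start_cid = min(graph.contigs)
    solutions: dict[tuple, CircleWalk] = {}
    truncated = False

    def backtrack(path: list[Step], remaining: dict[str, int]) -> None:
        nonlocal truncated
        if len(solutions) >= max_solutions:
            truncated = True
            return
        if len(path) == total_steps:
            # closed iff a connection leads back to the start step
            for nxt in trans.get(path[-1], []):
                if nxt == path[0]:
                    walk = CircleWalk(tuple(path))
                    solutions.setdefault(walk.canonical(), walk)
                    break
            return
        for nxt in trans.get(path[-1], []):
            cid = nxt[0]
            if remaining.get(cid, 0) > 0:
                remaining[cid] -= 1
                path.append(nxt)
                backtrack(path, remaining)
                path.pop()
                remaining[cid] += 1

    remaining = dict(copies)
    remaining[start_cid] -= 1
    backtrack([(start_cid, "+")], remaining)
    # a reflection-symmetric graph may only be traversable starting '-'
    remaining = dict(copies)
    remaining[start_cid] -= 1
    backtrack([(start_cid, "-")], remaining)

    if not solutions:
        dead = []
        for cid in sorted(graph.contigs):
            for orient in "+-":
                if (cid, orient) not in trans:
                    dead.append(f"{cid}{orient} (no connection at side "
                                f"{_exit_side(orient)})")
        raise AssemblyGapError(
            "no closed walk covers all contig copies; unsatisfiable ends: "
            + (", ".join(dead) if dead else "copy counts inconsistent with topology")
        )
    walks = [solutions[k] for k in sorted(solutions)]
    if truncated:
        import warnings

        warnings.warn(f"stopped at max_solutions={max_solutions}; "
                      "enumeration incomplete", RuntimeWarning)
    return walks


def _connection_exists(graph: ContigGraph, step_a: Step, step_b: Step) -> bool:
    ep_a = (step_a[0], _exit_side(step_a[1]))
    side_b = "L" if step_b[1] == "+" else "R"
    ep_b = (step_b[0], side_b)
    want = frozenset([ep_a, ep_b]) if ep_a != ep_b else frozenset([ep_a])
    return any(c.key() == want for c in graph.connections)


def concatenate(walk: CircleWalk, graph: ContigGraph,
                min_junction_overlap: int = 20) -> GenomeSequence:
    """Join the walk's contig sequences into one circular sequence.

    At each junction an exact suffix-prefix overlap of at least
    ``min_junction_overlap`` nt is collapsed once (longest such overlap);
    otherwise the sequences abut.  The closing junction back to the first
    contig is treated the same way.
    """
    oriented: list[str] = []
    for i, (cid, orient) in enumerate(walk.steps):
        contig = graph.contigs.get(cid)
        if contig is None or contig.residues is None:
            raise ValueError(f"contig {cid} has no residues loaded")
        nxt = walk.steps[(i + 1) % len(walk.steps)]
        if not _connection_exists(graph, (cid, orient), nxt):
            raise ValueError(
                f"junction {cid}({orient}) -> {nxt[0]}({nxt[1]}) has no "
                "side-compatible connection"
            )
        oriented.append(contig.residues if orient == "+" else revcomp(contig.residues))

    def overlap(a: str, b: str) -> int:
        limit = min(len(a), len(b))
        for n in range(limit, min_junction_overlap - 1, -1):
            if a[-n:] == b[:n]:
                return n
        return 0

    seq = oriented[0]
    for part in oriented[1:]:
        n = overlap(seq, part)
        seq += part[n:]
    n = overlap(seq, seq)  # wrap junction: tail vs head of the circle
    if 0 < n < len(seq):
        seq = seq[: len(seq) - n]
    name = "-".join(f"{cid}{o}" for cid, o in walk.steps)
    return GenomeSequence(SequenceRecord("circle_" + name, seq), "circular")


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically least rotation in O(n)."""
    s2 = s + s
    n = len(s2)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s2[k : k + len(s)]


def canonical_form(genome: GenomeSequence | str) -> str:
    """Rotation- and strand-invariant string for a circular sequence.

    Defined as the lexicographically least rotation over both strands;
    idempotent, and identical for every rotation/reflection of one circle.
    """
    seq = genome if isinstance(genome, str) else genome.seq
    if not seq:
        return ""
    return min(_least_rotation(seq), _least_rotation(revcomp(seq)))


@dataclass
class SubCirclePair:
    parent_length: int
    repeat_label: str
    child1: GenomeSequence
    child2: GenomeSequence


def enumerate_subcircles(parent: GenomeSequence, repeat) -> SubCirclePair:
    """Split a master circle across a direct repeat pair into two sub-circles.

    ``repeat`` needs attributes interval1, interval2 (0-based half-open on the
    parent, copy 1 before copy 2) and orientation ('direct'/'inverted').
    Child 1 runs from the start of copy 1 to the start of copy 2 (one repeat
    copy plus the intervening arc); child 2 is the complementary arc plus the
    other copy.  Child lengths sum to the parent length.  Inverted pairs are
    rejected: recombination across them inverts the intervening segment and
    yields another master circle, not a fission.
    """
    if repeat.orientation != "direct":
        raise ValueError(
            "recombination across an inverted repeat yields an inversion "
            "isomer, not sub-circles; only direct repeats are modelled"
        )
    L = len(parent)
    s1, s2 = repeat.interval1.start, repeat.interval2.start
    if not (0 <= s1 < s2 < L):
        raise ValueError("repeat copies must be ordered on the parent")
    child1 = parent.seq[s1:s2]
    child2 = parent.seq[s2:] + parent.seq[:s1]
    label = getattr(repeat, "label", f"{s1}-{s2}")
    return SubCirclePair(
        parent_length=L,
        repeat_label=str(label),
        child1=GenomeSequence(SequenceRecord("subcircle1", child1), "circular"),
        child2=GenomeSequence(SequenceRecord("subcircle2", child2), "circular"),
    )
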