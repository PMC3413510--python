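"""Paired-end concordance validation of a circular assembly.

A pair is *in agreement* when any combination of qualifying placements of its
two ends (opposite strands, facing inward) sits within the expected insert
range; it *disagrees* when both ends place somewhere qualifying but no
combination is in range, and is *not evaluable* otherwise.  Qualifying means
at least ``min_end_length`` aligned bases, identity and read-fraction above
their thresholds — the same dual thresholds the mapper reports.

Separation is measured from the leftmost aligned base of the forward-strand
placement along the inward-facing arc to the rightmost aligned base of the
reverse-strand placement (outer distance — the natural reading of insert size
for a 3 kb jumping library on a circle).

Disagreements are then attributed: placements near a repeat boundary multi-map
across repeat copies (repeat-border); placements inside a segment shared with
another organelle genome can be concordant there instead
(shared-with-other-genome); the rest are unexplained and point at true
mis-joins.
"""

from __future__ import annotations

from dataclasses import dataclass

from .maplite import Alignment, ReadIndex, map_read
from .seqio import GenomeSequence, Interval


@dataclass
class PairClassification:
    pair_id: str
    status: str  # agree / disagree / not-evaluable
    placement1: Alignment | None = None
    placement2: Alignment | None = None
    separation: int | None = None
    category: str | None = None  # repeat-border / shared-with-other-genome / unexplained


def _circular_separation(plus: Alignment, minus: Alignment, L: int) -> int:
    """Outer distance along the inward arc: + read start -> - read end."""
    start = plus.interval.start
    end = minus.interval.end
    if minus.interval.start > minus.interval.end:  # wraps: rightmost base is `end`
        pass
    return (end - start) % L or L


def _qualifies(a: Alignment, min_end_length: int) -> bool:
    return (a.read_end - a.read_start) >= min_end_length


def classify_pairs(pairs1, pairs2, genome: GenomeSequence,
                   min_end_length: int = 50, min_identity: float = 0.95,
                   min_read_fraction: float = 0.85,
                   insert_range: tuple[int, int] = (1000, 5000),
                   k: int = 17) -> list[PairClassification]:
    """Classify read pairs against the assembly.

    ``pairs1`` and ``pairs2`` are the two end files in matching order.
    """
    if len(pairs1) != len(pairs2):
        raise ValueError(
            f"mismatched pair files: {len(pairs1)} vs {len(pairs2)} reads"
        )
    L = len(genome)
    lo, hi = insert_range
    max_len = max((len(r.residues) for r in list(pairs1) + list(pairs2)), default=150)
    idx = ReadIndex(genome, k, extension=max_len + 16)
    out: list[PairClassification] = []
    for r1, r2 in zip(pairs1, pairs2):
        pid = r1.id.rsplit("/", 1)[0]
        p1 = [a for a in map_read(r1, idx, min_identity, min_read_fraction)
              if _qualifies(a, min_end_length)]
        p2 = [a for a in map_read(r2, idx, min_identity, min_read_fraction)
              if _qualifies(a, min_end_length)]
        if not p1 or not p2:
            out.append(PairClassification(pid, "not-evaluable"))
            continue
        best: tuple[int, Alignment, Alignment] | None = None
        agree_combo = None
        for a in p1:
            for b in p2:
                if a.strand == b.strand:
                    continue
                plus, minus = (a, b) if a.strand == "+" else (b, a)
                sep = _circular_separation(plus, minus, L)
                if lo <= sep <= hi:
                    agree_combo = (sep, a, b)
                    break
                dist = min(abs(sep - lo), abs(sep - hi))
                if best is None or dist < best[0]:
                    best = (dist, a, b)
                    best_sep = sep
            if agree_combo:
                break
        if agree_combo:
            sep, a, b = agree_combo
            out.append(PairClassification(pid, "agree", a, b, sep))
        elif best is not None:
            _, a, b = best
            out.append(PairClassification(pid, "disagree", a, b, best_sep))
        else:  # both ends place but never on opposite strands
            out.append(PairClassification(pid, "disagree", p1[0], p2[0], None))
    return out


def _near_boundary(a: Alignment, intervals, margin: int, L: int) -> bool:
    """Does the aligned interval come within ``margin`` of an interval edge?"""
    s, e = a.interval.start, a.interval.end
    positions = range(s, e) if s <= e else list(range(s, L)) + list(range(0, e))
    for iv in intervals:
        for edge in (iv.start, iv.end):
            lo = (edge - margin) % L
            hi = (edge + margin) % L
            win = Interval(iv.target, lo, hi) if lo != hi else None
            if win is None:
                return True
            if s <= e:
                if win.start <= win.end:
                    if not (e <= win.start or s >= win.end):
                        return True
                else:
                    if e > win.start or s < win.end:
                        return True
            else:
                # read interval wraps; windows are small, test both arcs
                if win.contains(s) or win.contains((e - 1) % L) or \
                   Interval("x", s, e).contains(win.start):
                    return True
    return False


def _inside(a: Alignment, intervals, L: int) -> bool:
    s = a.interval.start
    mid = (s + a.aligned_length // 2) % L
    return any(iv.contains(s) or iv.contains(mid) for iv in intervals)


def categorize_discordant(classifications, repeat_intervals,
                          shared_intervals, genome_length: int,
                          border_margin: int = 100) -> list[PairClassification]:
    """Attribute each disagreement to a cause, repeat-border taking precedence."""
    for c in classifications:
        if c.status != "disagree":
            continue
        ends = [p for p in (c.placement1, c.placement2) if p is not None]
        if any(_near_boundary(a, repeat_intervals, border_margin, genome_length)
               for a in ends):
            c.category = "repeat-border"
        elif any(_inside(a, shared_intervals, genome_length) for a in ends):
            c.category = "shared-with-other-genome"
        else:
            c.category = "unexplained"
    return classifications


def summary(classifications) -> dict:
    counts = {"agree": 0, "disagree": 0, "not-evaluable": 0}
    categories: dict[str, int] = {}
    for c in classifications:
        counts[c.status] += 1
        if c.category:
            categories[c.category] = categories.get(c.category, 0) + 1
    evaluable = counts["agree"] + counts["disagree"]
    return dict(
        total=len(classifications), **counts,
        agree_fraction=counts["agree"] / evaluable if evaluable else float("nan"),
        categories=categories,
    )


def write_pair_tsv(classifications, path) -> None:
    with open(path, "w") as fh:
        fh.write("pair\tstatus\tseparation\tcategory\tpos1\tstrand1\tpos2\tstrand2\n")
        for c in classifications:
            p1 = c.placement1.interval.start if c.placement1 else ""
            s1 = c.placement1.strand if c.placement1 else ""
            p2 = c.placement2.interval.start if c.placement2 else ""
            s2 = c.placement2.strand if c.placement2 else ""
            sep = c.separation if c.separation is not None else ""
            fh.write(f"{c.pair_id}\t{c.status}\t{sep}\t{c.category or ''}\t"
                     f"{p1}\t{s1}\t{p2}\t{s2}\n")


def write_link_table(classifications, target_id: str, path) -> None:
    """Circos-style link table (target, posA, posB, status)."""
    with open(path, "w") as fh:
        fh.write("target\tposA\tposB\tstatus\n")
        for c in classifications:
            if c.placement1 is None or c.placement2 is None:
                continue
            fh.write(f"{target_id}\t{c.placement1.interval.start}\t"
                     f"{c.placement2.interval.start}\t{c.status}\n")
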