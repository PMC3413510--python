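"""Dispersed-repeat detection, in-silico restriction digestion, band prediction.

Repeats are found by k-mer seeded self-comparison of the genome against itself
(direct) and its reverse complement (inverted), chaining seeds on a common
diagonal, extending exactly outward, and scoring identity over the aligned
columns.  Digestion expands IUPAC recognition sites on both strands
(palindrome-aware) and assembles fragments per topology; a Southern lane is
predicted as the union, over co-existing genome conformations, of the
fragments a probe hybridizes to.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .seqio import GenomeSequence, Interval, revcomp

IUPAC_REGEX = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class RepeatPair:
    interval1: Interval
    interval2: Interval
    orientation: str  # direct / inverted
    identity: float
    length: int  # aligned nt
    tandem: bool = False
    label: str = ""


# ---------------------------------------------------------------------------
# repeat detection


def _seed_hits(query: str, target: str, k: int):
    """Diagonal -> sorted query offsets of exact shared k-mers."""
    index: dict[str, list[int]] = {}
    for j in range(len(target) - k + 1):
        index.setdefault(target[j : j + k], []).append(j)
    diags: dict[int, list[int]] = {}
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            diags.setdefault(j - i, []).append(i)
    return diags


def _chain_diagonal(offsets: list[int], k: int, max_gap: int = 30):
    """Merge seed offsets on one diagonal into runs (start, end on query)."""
    runs = []
    offsets = sorted(offsets)
    lo = hi = offsets[0]
    for i in offsets[1:]:
        if i <= hi + k + max_gap:
            hi = i
        else:
            runs.append((lo, hi + k))
            lo = hi = i
    runs.append((lo, hi + k))
    return runs


def _extend_exact(query: str, target: str, q_lo: int, q_hi: int, d: int):
    """Greedy exact extension of a same-diagonal run in both directions."""
    while q_lo > 0 and 0 < q_lo + d and query[q_lo - 1] == target[q_lo - 1 + d]:
        q_lo -= 1
    while q_hi < len(query) and q_hi + d < len(target) and \
            query[q_hi] == target[q_hi + d]:
        q_hi += 1
    return q_lo, q_hi


def find_repeats(genome: GenomeSequence, min_length: int = 40,
                 min_identity: float = 0.90, k: int = 14,
                 max_gap: int = 30) -> list[RepeatPair]:
    """Repeat pairs within one genome, mirror-deduplicated.

    The second copy's strand gives the orientation; layout-adjacent copies are
    flagged tandem but reported like dispersed pairs.
    """
    seq = genome.seq
    L = len(seq)
    tid = genome.record.id
    pairs: dict[tuple, RepeatPair] = {}

    def record(i1: int, i2: int, n: int, orientation: str, ident: float) -> None:
        # i1/i2: starts on the forward strand, n aligned length
        if orientation == "direct":
            a = (i1, i1 + n)
            b = (i2, i2 + n)
        else:
            a = (i1, i1 + n)
            b = (i2, i2 + n)
        if a == b:
            return  # self-match (palindrome centre)
        if a > b:
            a, b = b, a
        key = (a, b, orientation)
        if key in pairs:
            return
        tandem = a[1] == b[0] or b[1] % L == a[0]
        pairs[key] = RepeatPair(
            Interval(tid, a[0], a[1], "+"),
            Interval(tid, b[0], b[1], "+" if orientation == "direct" else "-"),
            orientation, ident, n, tandem=tandem,
        )

    def identity_of(s1: str, s2: str) -> float:
        if s1 == s2:
            return 1.0
        res = edlib.align(s1, s2, mode="NW", task="distance")
        cols = max(len(s1), len(s2))
        return 1.0 - res["editDistance"] / cols

    # direct: genome vs itself, diagonal 0 excluded
    for d, offsets in _seed_hits(seq, seq, k).items():
        if d <= 0:
            continue  # d<0 mirrors d>0; d==0 is the self-diagonal
        for q_lo, q_hi in _chain_diagonal(offsets, k, max_gap):
            q_lo, q_hi = _extend_exact(seq, seq, q_lo, q_hi, d)
            n = q_hi - q_lo
            if n < min_length:
                continue
            ident = identity_of(seq[q_lo:q_hi], seq[q_lo + d : q_hi + d])
            if ident >= min_identity:
                record(q_lo, q_lo + d, n, "direct", ident)

    # inverted: genome vs its reverse complement
    rc = revcomp(seq)
    for d, offsets in _seed_hits(seq, rc, k).items():
        for q_lo, q_hi in _chain_diagonal(offsets, k, max_gap):
            q_lo, q_hi = _extend_exact(seq, rc, q_lo, q_hi, d)
            n = q_hi - q_lo
            if n < min_length:
                continue
            # rc interval [q_lo+d, q_hi+d) maps to forward [L-q_hi-d, L-q_lo-d)
            f_lo = L - (q_hi + d)
            f_hi = L - (q_lo + d)
            if f_lo < 0:
                continue
            ident = identity_of(seq[q_lo:q_hi], rc[q_lo + d : q_hi + d])
            if ident >= min_identity:
                record(q_lo, f_lo, n, "inverted", ident)
    return sorted(pairs.values(),
                  key=lambda p: (p.interval1.start, p.interval2.start, p.orientation))


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
    return total + (cur_hi - cur_lo)


DEFAULT_BINS = ((20, 40), (41, 60), (61, 80), (81, 100), (101, 202),
                (203, 4219), (4220, 10**9))


def repeat_report(pairs: list[RepeatPair], genome_length: int,
                  bins=DEFAULT_BINS) -> pd.DataFrame:
    """Length-binned repeat counts, orientations, and genome coverage percent."""
    rows = []
    all_intervals = []
    for p in pairs:
        for iv in (p.interval1, p.interval2):
            all_intervals.append((iv.start, iv.end))
    for lo, hi in bins:
        sub = [p for p in pairs if lo <= p.length <= hi]
        ivs = []
        for p in sub:
            for iv in (p.interval1, p.interval2):
                ivs.append((iv.start, iv.end))
        rows.append(dict(
            bin=f"{lo}-{hi if hi < 10**9 else ''}",
            count=len(sub),
            direct=sum(p.orientation == "direct" for p in sub),
            inverted=sum(p.orientation == "inverted" for p in sub),
            coverage_pct=100.0 * _union_length(ivs) / genome_length,
        ))
    rows.append(dict(
        bin="total", count=len(pairs),
        direct=sum(p.orientation == "direct" for p in pairs),
        inverted=sum(p.orientation == "inverted" for p in pairs),
        coverage_pct=100.0 * _union_length(all_intervals) / genome_length,
    ))
    return pd.DataFrame(rows).set_index("bin")


@dataclass
class SuperRepeatBlock:
    start: int
    end: int
    members: list[RepeatPair] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_super_repeats(pairs: list[RepeatPair], max_gap: int = 0) -> list[SuperRepeatBlock]:
    """Merge repeat intervals separated by <= max_gap into super-repeat blocks."""
    items = []
    for p in pairs:
        for iv in (p.interval1, p.interval2):
            items.append((iv.start, iv.end, p))
    items.sort(key=lambda t: (t[0], t[1]))
    blocks: list[SuperRepeatBlock] = []
    for lo, hi, p in items:
        if blocks and lo <= blocks[-1].end + max_gap:
            blocks[-1].end = max(blocks[-1].end, hi)
            if p not in blocks[-1].members:
                blocks[-1].members.append(p)
        else:
            blocks.append(SuperRepeatBlock(lo, hi, [p]))
    return blocks


# ---------------------------------------------------------------------------
# digestion


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str  # IUPAC, top strand
    cut_offset: int  # within [0, len(recognition)]

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError("recognition site must be >= 4 nt")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut offset outside the recognition site")
        if any(b not in IUPAC_REGEX for b in self.recognition.upper()):
            raise ValueError(f"bad IUPAC recognition {self.recognition!r}")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition.upper() == revcomp(self.recognition.upper())


XHOI = Enzyme("XhoI", "CTCGAG", 1)          # C^TCGAG
EAM1105I = Enzyme("Eam1105I", "GACNNNNNGTC", 6)  # GACNNN^NNGTC
ENZYMES = {e.name: e for e in (XHOI, EAM1105I)}


@dataclass
class Fragment:
    start: int
    end: int  # start > end means origin-spanning on a circle
    length: int


@dataclass
class FragmentSet:
    topology: str
    enzyme: str
    fragments: list[Fragment]
    uncut: bool = False

    @property
    def lengths(self) -> list[int]:
        return [f.length for f in self.fragments]


def _iupac_pattern(site: str) -> re.Pattern:
    return re.compile("".join(IUPAC_REGEX[b] for b in site.upper()))


def cut_positions(genome: GenomeSequence, enzyme: Enzyme) -> list[int]:
    """Top-strand cut coordinates from both-strand site matches (deduplicated)."""
    seq = genome.seq
    L = len(seq)
    m = len(enzyme.recognition)
    search = seq + seq[: m - 1] if genome.topology == "circular" else seq
    cuts = set()
    pat_f = _iupac_pattern(enzyme.recognition)
    for hit in pat_f.finditer(search):
        cuts.add((hit.start() + enzyme.cut_offset) % L if genome.topology == "circular"
                 else hit.start() + enzyme.cut_offset)
    if not enzyme.is_palindromic:
        pat_r = _iupac_pattern(revcomp(enzyme.recognition))
        for hit in pat_r.finditer(search):
            cut = hit.start() + (m - enzyme.cut_offset)
            cuts.add(cut % L if genome.topology == "circular" else cut)
    if genome.topology == "linear":
        cuts = {c for c in cuts if 0 < c < L}
    return sorted(cuts)


def digest(genome: GenomeSequence, enzyme: Enzyme) -> FragmentSet:
    """Fragment the genome at every enzyme site.

    Circular with s >= 1 sites -> s fragments summing to the genome length;
    linear with s sites -> s + 1 fragments; an uncut circle yields one
    flagged full-length pseudo-fragment.
    """
    L = len(genome)
    cuts = cut_positions(genome, enzyme)
    if genome.topology == "circular":
        if not cuts:
            return FragmentSet("circular", enzyme.name,
                               [Fragment(0, L, L)], uncut=True)
        frags = []
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            length = (nxt - c) % L or L
            frags.append(Fragment(c, nxt, length))
        return FragmentSet("circular", enzyme.name, frags)
    bounds = [0] + cuts + [L]
    frags = [Fragment(a, b, b - a) for a, b in zip(bounds, bounds[1:]) if b > a]
    return FragmentSet("linear", enzyme.name, frags)


def _overlaps_circular(frag: Fragment, probe: Interval, L: int) -> bool:
    if frag.length >= L:
        return True  # uncut circle overlaps everything
    f_arcs = [(frag.start, frag.end)] if frag.start < frag.end \
        else [(frag.start, L), (0, frag.end)]
    p_arcs = [(probe.start, probe.end)] if probe.start < probe.end \
        else [(probe.start, L), (0, probe.end)]
    for fs, fe in f_arcs:
        for ps, pe in p_arcs:
            if max(fs, ps) < min(fe, pe):
                return True
    return False


def southern_predict(fragment_sets: dict[str, FragmentSet],
                     probes: dict[str, Interval],
                     lengths: dict[str, int]) -> pd.DataFrame:
    """Predicted hybridization bands per conformation, plus the lane union.

    ``fragment_sets``/``probes``/``lengths`` are keyed by conformation name
    (probe coordinates projected onto each conformation).  A conformation
    whose probe is missing contributes no bands.
    """
    rows = []
    for name, fset in fragment_sets.items():
        probe = probes.get(name)
        if probe is None:
            import warnings

            warnings.warn(f"probe absent from conformation {name}; no bands")
            continue
        L = lengths[name]
        for frag in fset.fragments:
            if _overlaps_circular(frag, probe, L):
                rows.append(dict(conformation=name, enzyme=fset.enzyme,
                                 start=frag.start, end=frag.end,
                                 band_length=frag.length))
    df = pd.DataFrame(rows, columns=["conformation", "enzyme", "start", "end",
                                     "band_length"])
    return df.sort_values(["conformation", "band_length"],
                          ignore_index=True) if len(df) else df
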