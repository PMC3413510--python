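"""Cross-genome comparison and DNA-transfer detection machinery.

Shared segments between two genomes (e.g. plastid-like stretches inside a
mitochondrial genome) are found by the same seed-chain-extend strategy the
repeat scanner uses, clipped at masked positions.  Flank-anchored insertion
scanning locates two flanking sequences in a target genome and reports the
intervening stretch — the in-silico counterpart of amplifying across an
insertion locus.  In-silico PCR predicts amplicons with mismatch-tolerant
primer matching that still requires a perfect 3'-terminal 3-mer (extension
competence), and the ORF scanner enumerates start-to-stop reading frames in
all six frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .maplite import ReadIndex, map_read
from .repeatscan import _chain_diagonal, _extend_exact, _seed_hits
from .seqio import GenomeSequence, Interval, SequenceRecord, revcomp

import edlib


@dataclass(frozen=True)
class SharedSegment:
    interval_a: Interval
    interval_b: Interval
    identity: float
    length: int
    interrupted_by_mask: bool = False


def _identity(s1: str, s2: str) -> float:
    if s1 == s2:
        return 1.0
    d = edlib.align(s1, s2, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(s1), len(s2))


def shared_segments(genome_a: GenomeSequence, genome_b: GenomeSequence,
                    min_length: int = 40, min_identity: float = 0.90,
                    mask_intervals: tuple[Interval, ...] = (),
                    k: int = 14, max_gap: int = 30) -> list[SharedSegment]:
    """Segments of A matching B (either strand), clipped at masked A positions."""
    a, b = genome_a.seq, genome_b.seq
    ida, idb = genome_a.record.id, genome_b.record.id
    Lb = len(b)
    masked = np.zeros(len(a), dtype=bool)
    for iv in mask_intervals:
        if iv.start <= iv.end:
            masked[iv.start : iv.end] = True
        else:
            masked[iv.start :] = True
            masked[: iv.end] = True

    segments: list[SharedSegment] = []

    def emit(a_lo: int, a_hi: int, strand: str, b_of_a):
        """Split [a_lo, a_hi) at masked positions and report qualifying parts."""
        was_clipped = bool(masked[a_lo:a_hi].any())
        pos = a_lo
        while pos < a_hi:
            while pos < a_hi and masked[pos]:
                pos += 1
            end = pos
            while end < a_hi and not masked[end]:
                end += 1
            if end - pos >= min_length:
                b_lo, b_hi = b_of_a(pos, end)
                sa = a[pos:end]
                sb = b[b_lo:b_hi] if strand == "+" else revcomp(b[b_lo:b_hi])
                ident = _identity(sa, sb)
                if ident >= min_identity:
                    segments.append(SharedSegment(
                        Interval(ida, pos, end, "+"),
                        Interval(idb, b_lo, b_hi, strand),
                        ident, end - pos, interrupted_by_mask=was_clipped,
                    ))
            pos = end

    for d, offsets in _seed_hits(a, b, k).items():
        for lo, hi in _chain_diagonal(offsets, k, max_gap):
            lo, hi = _extend_exact(a, b, lo, hi, d)
            if hi - lo >= min_length:
                emit(lo, hi, "+", lambda p, e, d=d: (p + d, e + d))

    rc_b = revcomp(b)
    for d, offsets in _seed_hits(a, rc_b, k).items():
        for lo, hi in _chain_diagonal(offsets, k, max_gap):
            lo, hi = _extend_exact(a, rc_b, lo, hi, d)
            if hi - lo >= min_length:
                emit(lo, hi, "-",
                     lambda p, e, d=d: (Lb - (e + d), Lb - (p + d)))

    uniq = {}
    for s in segments:
        key = (s.interval_a.start, s.interval_a.end,
               s.interval_b.start, s.interval_b.strand)
        if key not in uniq or s.identity > uniq[key].identity:
            uniq[key] = s
    return sorted(uniq.values(), key=lambda s: (s.interval_a.start, s.interval_b.start))


def similarity_fraction(genome_a: GenomeSequence, genome_b: GenomeSequence,
                        min_length: int = 50, min_identity: float = 0.80,
                        k: int = 14) -> float:
    """Fraction of A covered by the union of qualifying matches to B."""
    segs = shared_segments(genome_a, genome_b, min_length, min_identity, k=k)
    covered = np.zeros(len(genome_a), dtype=bool)
    for s in segs:
        covered[s.interval_a.start : s.interval_a.end] = True
    return float(covered.mean())


# ---------------------------------------------------------------------------
# flank-anchored insertion scan


@dataclass
class InsertionCall:
    genome_id: str
    status: str  # insertion-present / reference-like / flank-missing / ambiguous
    left_hit: Interval | None = None
    right_hit: Interval | None = None
    intervening_length: int | None = None
    intervening_sequence: str | None = None
    placements: list = field(default_factory=list)


def flank_insertion_scan(left_flank: str, right_flank: str,
                         genomes: dict[str, GenomeSequence],
                         min_flank_identity: float = 0.90,
                         k: int = 15,
                         max_intervening: int = 50_000) -> list[InsertionCall]:
    """Locate both flanks in each genome and report what lies between them.

    Flanks must place colinearly on the same strand; a genome where they abut
    is reference-like, one with intervening sequence carries an insertion, and
    a missing flank (or an ambiguous tie of equal-best placements) is reported
    as such.
    """
    if min(len(left_flank), len(right_flank)) < 30:
        raise ValueError("flanks must be >= 30 nt")
    calls = []
    for gid, genome in sorted(genomes.items()):
        idx = ReadIndex(genome, k,
                        extension=max(len(left_flank), len(right_flank)) + 16)
        hits = {}
        ambiguous = False
        placements = []
        for name, flank in (("left", left_flank), ("right", right_flank)):
            rec = SequenceRecord(name, flank)
            alns = map_read(rec, idx, min_identity=min_flank_identity,
                            min_read_fraction=0.9)
            if not alns:
                hits[name] = None
                continue
            best = [a for a in alns if a.score == alns[0].score]
            placements.append((name, best))
            if len(best) > 1:
                ambiguous = True
            hits[name] = best[0]
        if hits.get("left") is None or hits.get("right") is None:
            calls.append(InsertionCall(gid, "flank-missing",
                                       hits.get("left") and hits["left"].interval,
                                       hits.get("right") and hits["right"].interval))
            continue
        if ambiguous:
            calls.append(InsertionCall(
                gid, "ambiguous",
                hits["left"].interval, hits["right"].interval,
                placements=[(n, [a.interval for a in b]) for n, b in placements],
            ))
            continue
        lh, rh = hits["left"], hits["right"]
        if lh.strand != rh.strand:
            calls.append(InsertionCall(gid, "flank-missing",
                                       lh.interval, rh.interval))
            continue
        L = len(genome)
        if lh.strand == "+":
            gap = (rh.interval.start - lh.interval.end) % L
            seq = genome.fetch(lh.interval.end, lh.interval.end + gap) if gap else ""
        else:
            gap = (lh.interval.start - rh.interval.end) % L
            seq = revcomp(genome.fetch(rh.interval.end, rh.interval.end + gap)) \
                if gap else ""
        if gap > max_intervening:
            calls.append(InsertionCall(gid, "flank-missing",
                                       lh.interval, rh.interval))
            continue
        status = "insertion-present" if gap > 0 else "reference-like"
        calls.append(InsertionCall(gid, status, lh.interval, rh.interval,
                                   gap, seq))
    return calls


# ---------------------------------------------------------------------------
# in-silico PCR


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    max_mismatches: int = 0
    max_product: int = 10_000

    def __post_init__(self) -> None:
        if min(len(self.forward), len(self.reverse)) < 15:
            raise ValueError("primers must be >= 15 nt")
        if self.max_product <= len(self.forward) + len(self.reverse):
            raise ValueError("max product must exceed the primer lengths")


@dataclass(frozen=True)
class Amplicon:
    start: int  # 5' of the forward-matching primer, 0-based
    end: int  # one past the 5' of the reverse primer (may exceed L: wraps)
    length: int
    strand: str  # strand the `forward` primer annealed to


def _primer_sites(seq: str, primer: str, max_mm: int, three_prime_left: bool) -> np.ndarray:
    """Start positions where the primer matches with <= max_mm mismatches.

    The 3'-terminal 3-mer must match exactly; ``three_prime_left`` marks
    primers whose 3' end maps to the left (start) of the window.
    """
    m = len(primer)
    if len(seq) < m:
        return np.array([], dtype=int)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, m)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    mm = (win != p).sum(axis=1)
    exact3 = (win[:, :3] == p[:3]).all(axis=1) if three_prime_left \
        else (win[:, -3:] == p[-3:]).all(axis=1)
    return np.nonzero((mm <= max_mm) & exact3)[0]


def insilico_pcr(genome: GenomeSequence, primers: PrimerPair) -> list[Amplicon]:
    """Predicted amplicons on the template (both primer arrangements).

    Amplicon length is 5'-to-5' inclusive, the convention gel sizes use.
    Circular templates allow origin-spanning products.
    """
    L = len(genome)
    circular = genome.topology == "circular"
    ext = min(primers.max_product, L) if circular else 0
    seq = genome.seq + genome.seq[:ext]
    out = set()
    for fwd, rev, strand in ((primers.forward, primers.reverse, "+"),
                             (primers.reverse, primers.forward, "-")):
        f_sites = _primer_sites(seq, fwd, primers.max_mismatches, False)
        r_sites = _primer_sites(seq, revcomp(rev), primers.max_mismatches, True)
        if len(f_sites) == 0 or len(r_sites) == 0:
            continue
        r_ends = r_sites + len(rev)  # one past the reverse primer's 5' base
        seen = set()
        for f in f_sites:
            if circular and f >= L:
                continue
            for re_ in r_ends:
                length = re_ - f
                if circular and length > L:
                    continue  # same physical site pair seen through the extension
                if (len(fwd) + len(rev) <= length <= primers.max_product
                        and re_ - len(rev) >= f + len(fwd)):
                    key = (f % L, re_ % L) if circular else (f, re_)
                    if key not in seen:
                        seen.add(key)
                        out.add(Amplicon(int(f), int(re_), int(length), strand))
    return sorted(out, key=lambda a: (a.start, a.length, a.strand))


# ---------------------------------------------------------------------------
# ORF scanning


@dataclass(frozen=True)
class OpenReadingFrame:
    interval: Interval
    length: int  # nt, stop codon included
    protein: str


STOPS = {"TAA", "TAG", "TGA"}
START = "ATG"


def _scan_frames(seq: str):
    """(start, end) of start-to-stop ORFs in all three forward frames of seq."""
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOPS:
                if start is not None:
                    yield start, i + 3
                start = None
            elif codon == START and start is None:
                start = i
    return


def orf_scan(genome: GenomeSequence, min_length: int = 300) -> list[OpenReadingFrame]:
    """Start-codon-initiated, stop-terminated ORFs >= min_length in six frames.

    On circular genomes the scan runs over the doubled sequence so frames may
    cross the origin; ORFs longer than the genome are impossible and dropped.
    """
    L = len(genome)
    tid = genome.record.id
    circular = genome.topology == "circular"
    out: dict[tuple, OpenReadingFrame] = {}

    fwd = genome.seq + (genome.seq if circular else "")
    for fs, fe in _scan_frames(fwd):
        if circular and fs >= L:
            continue
        length = fe - fs
        if length < min_length or length > L:
            continue
        start = fs % L if circular else fs
        end = start + length
        end = end if end <= L else end - L
        key = (start, length, "+")
        if key in out:
            continue
        protein = str(Seq(fwd[fs:fe]).translate())
        out[key] = OpenReadingFrame(Interval(tid, start, end, "+"), length, protein)

    rc = revcomp(genome.seq)
    rc_scan = rc + (rc if circular else "")
    for fs, fe in _scan_frames(rc_scan):
        if circular and fs >= L:
            continue
        length = fe - fs
        if length < min_length or length > L:
            continue
        # map rc coords back to forward strand
        r_start = fs % L if circular else fs
        f_end = L - r_start
        f_start = f_end - length
        start = f_start % L
        end = start + length
        end = end if end <= L else end - L
        key = (start, length, "-")
        if key in out:
            continue
        s = rc_scan[fs:fe]
        protein = str(Seq(s).translate())
        out[key] = OpenReadingFrame(Interval(tid, start, end, "-"), length, protein)
    return sorted(out.values(), key=lambda o: (o.interval.start, o.length,
                                               o.interval.strand))
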