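"""Lightweight k-mer seed-and-extend read mapper with coverage accounting.

Reads are seeded by shared k-mers against the target (circular targets are
internally extended by one read length so placements may span the origin;
coordinates are reported modulo the genome length).  Candidate placements are
aligned with edlib and locally trimmed under unit-match scoring
(match +1, mismatch -1, gap -2), and every placement passing both the
identity (matches / aligned columns) and read-fraction (aligned read bases /
read length) thresholds is reported, best first.

The mapper is deliberately simple — organelle-scale targets, no spliced
alignment, no quality-aware scoring — but exact enough to score against
truth tables and an exhaustive aligner on small fixtures.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
from scipy import stats

from .seqio import GenomeSequence, Interval, SequenceRecord, revcomp

MATCH, MISMATCH, GAP = 1, -1, -2


@dataclass
class Alignment:
    read_id: str
    target_id: str
    interval: Interval  # strand carried here; start > end means origin-spanning
    identity: float
    read_fraction: float
    aligned_length: int  # aligned target nt
    matches: int
    score: int
    read_start: int  # aligned read bases [read_start, read_end)
    read_end: int
    cigar: str = ""

    @property
    def strand(self) -> str:
        return self.interval.strand


def _expand_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _columns_from_cigar(query: str, target: str, q0: int, t0: int, cigar: str):
    """Per-column (op, qpos, tpos) trace; op in {'=', 'X', 'I', 'D'}.

    'I' consumes query only (gap in target), 'D' target only.
    """
    q, t = q0, t0
    cols = []
    for n, op in _expand_cigar(cigar):
        if op == "=" :
            for _ in range(n):
                cols.append(("=", q, t)); q += 1; t += 1
        elif op == "X":
            for _ in range(n):
                cols.append(("X", q, t)); q += 1; t += 1
        elif op == "I":  # edlib: insertion to target = extra query base
            for _ in range(n):
                cols.append(("I", q, t)); q += 1
        elif op == "D":
            for _ in range(n):
                cols.append(("D", q, t)); t += 1
        else:
            raise ValueError(f"unexpected CIGAR op {op!r}")
    return cols


def _compress_cigar(ops) -> str:
    out = []
    prev, n = None, 0
    for op in ops:
        if op == prev:
            n += 1
        else:
            if prev is not None:
                out.append(f"{n}{prev}")
            prev, n = op, 1
    if prev is not None:
        out.append(f"{n}{prev}")
    return "".join(out)


def _local_trim(cols):
    """Best-scoring contiguous stretch of alignment columns (Kadane)."""
    best = (0, 0, 0)  # score, start, end
    cur, cur_start = 0, 0
    for i, (op, _q, _t) in enumerate(cols):
        sc = MATCH if op == "=" else (MISMATCH if op == "X" else GAP)
        if cur <= 0:
            cur, cur_start = sc, i
        else:
            cur += sc
        if cur > best[0]:
            best = (cur, cur_start, i + 1)
    return best


class ReadIndex:
    """k-mer index over the (extended) target sequence."""

    def __init__(self, genome: GenomeSequence, k: int = 17, extension: int = 500):
        self.genome = genome
        self.k = k
        L = len(genome)
        self.ext = min(extension, L) if genome.topology == "circular" else 0
        self.extended = genome.seq + genome.seq[: self.ext]
        self.index: dict[str, list[int]] = defaultdict(list)
        s = self.extended
        for i in range(len(s) - k + 1):
            self.index[s[i : i + k]].append(i)


def _candidate_windows(idx: ReadIndex, read: str, band: int = 16,
                       max_candidates: int = 64) -> list[tuple[int, int]]:
    k = idx.k
    diags = []
    for off in range(0, len(read) - k + 1):
        for pos in idx.index.get(read[off : off + k], ()):
            diags.append(pos - off)
    if not diags:
        return []
    diags = sorted(set(diags))
    clusters = []
    cur = [diags[0], diags[0]]
    for d in diags[1:]:
        if d - cur[1] <= band:
            cur[1] = d
        else:
            clusters.append(tuple(cur))
            cur = [d, d]
    clusters.append(tuple(cur))
    L = len(idx.genome)
    windows = []
    seen = set()
    for lo, hi in clusters[:max_candidates]:
        start = max(0, lo - band)
        end = min(len(idx.extended), hi + len(read) + band)
        key = (start % L, end - start)
        if key not in seen:
            seen.add(key)
            windows.append((start, end))
    return windows


def _gapless_columns(read: str, window: str):
    """Best gapless placement of the read inside the window, as columns."""
    if len(window) < len(read):
        return None
    arr = np.frombuffer(window.encode(), dtype=np.uint8)
    q = np.frombuffer(read.encode(), dtype=np.uint8)
    eq = np.lib.stride_tricks.sliding_window_view(arr, len(read)) == q
    t0 = int(eq.sum(axis=1).argmax())
    mask = eq[t0]
    return [("=" if m else "X", i, t0 + i) for i, m in enumerate(mask)]


def _align_window(read_id: str, read: str, strand: str, idx: ReadIndex,
                  win_start: int, win_end: int,
                  min_identity: float, min_read_fraction: float) -> Alignment | None:
    window = idx.extended[win_start:win_end]
    res = edlib.align(read, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    t_lo, t_hi = res["locations"][0]
    cols = _columns_from_cigar(read, window, 0, t_lo, res["cigar"])
    score, c0, c1 = _local_trim(cols)
    # edlib minimises edit distance, which can prefer a gap pair over two
    # mismatches; check the best gapless placement under our scoring too
    g_cols = _gapless_columns(read, window)
    if g_cols is not None:
        g_score, g0, g1 = _local_trim(g_cols)
        if g_score > score:
            cols, (score, c0, c1) = g_cols, (g_score, g0, g1)
    if c1 <= c0:
        return None
    seg = cols[c0:c1]
    matches = sum(1 for op, _, _ in seg if op == "=")
    aligned_cols = len(seg)
    read_lo = seg[0][1]
    read_hi = max(q for op, q, _ in seg if op != "D") + 1
    t_first = min(t for op, _, t in seg if op != "I")
    t_last = max(t for op, _, t in seg if op != "I") + 1
    identity = matches / aligned_cols
    if strand == "+":
        r_lo, r_hi = read_lo, read_hi
    else:  # coordinates on the original read
        r_lo, r_hi = len(read) - read_hi, len(read) - read_lo
    read_fraction = (read_hi - read_lo) / len(read)
    if identity < min_identity or read_fraction < min_read_fraction:
        return None
    L = len(idx.genome)
    abs_start = win_start + t_first
    abs_end = win_start + t_last
    if idx.genome.topology == "circular":
        start = abs_start % L
        end = start + (abs_end - abs_start)
        if end > L:
            end = end - L  # origin-spanning: Interval stores start > end
    else:
        start, end = abs_start, abs_end
    iv = Interval(idx.genome.record.id, start, end, strand)
    return Alignment(read_id, idx.genome.record.id, iv, identity, read_fraction,
                     aligned_length=abs_end - abs_start, matches=matches,
                     score=score, read_start=r_lo, read_end=r_hi,
                     cigar=_compress_cigar(op for op, _, _ in seg))


def map_read(read: SequenceRecord, idx: ReadIndex,
             min_identity: float = 0.95, min_read_fraction: float = 0.85,
             band: int = 16) -> list[Alignment]:
    """All qualifying placements of one read, best (highest score) first."""
    if len(read.residues) < idx.k:
        return []
    out: list[Alignment] = []
    for strand, seq in (("+", read.residues), ("-", revcomp(read.residues))):
        for win_start, win_end in _candidate_windows(idx, seq, band):
            aln = _align_window(read.id, seq, strand, idx, win_start, win_end,
                                min_identity, min_read_fraction)
            if aln is not None:
                out.append(aln)
    # deduplicate identical placements (origin-adjacent windows can repeat)
    uniq = {}
    for a in out:
        key = (a.interval.start, a.interval.end, a.strand)
        if key not in uniq or a.score > uniq[key].score:
            uniq[key] = a
    return sorted(uniq.values(), key=lambda a: (-a.score, a.interval.start, a.strand))


def map_reads(reads, genome: GenomeSequence, k: int = 17,
              min_identity: float = 0.95, min_read_fraction: float = 0.85,
              band: int = 16) -> tuple[list[Alignment], int]:
    """Map a read set; returns (alignments, count of reads shorter than k)."""
    if k < 11:
        raise ValueError("k must be >= 11")
    max_len = max((len(r.residues) for r in reads), default=100)
    idx = ReadIndex(genome, k, extension=max_len + band)
    alignments: list[Alignment] = []
    skipped = 0
    for read in reads:
        if len(read.residues) < k:
            skipped += 1
            continue
        alignments.extend(map_read(read, idx, min_identity, min_read_fraction, band))
    return alignments, skipped


# ---------------------------------------------------------------------------
# coverage and origin accounting


@dataclass
class CoverageTrack:
    target_id: str
    depth: np.ndarray  # per-base
    window: int
    window_depth: np.ndarray
    window_gc: np.ndarray
    gc_depth_correlation: float

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())


def coverage(alignments, genome: GenomeSequence, window: int = 500) -> CoverageTrack:
    """Per-base depth plus windowed depth/GC and their Pearson correlation."""
    L = len(genome)
    diff = np.zeros(L + 1)
    for a in alignments:
        s, e = a.interval.start, a.interval.end
        if s < e:
            diff[s] += 1
            diff[e] -= 1
        else:  # wraps the origin
            diff[s] += 1
            diff[L] -= 1
            diff[0] += 1
            diff[e] -= 1
    depth = np.cumsum(diff[:L])
    nwin = int(np.ceil(L / window))
    wdepth = np.array([depth[i * window : (i + 1) * window].mean() for i in range(nwin)])
    arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    isgc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
    wgc = np.array([isgc[i * window : (i + 1) * window].mean() for i in range(nwin)])
    if nwin > 2 and np.std(wdepth) > 0 and np.std(wgc) > 0:
        r = float(stats.pearsonr(wgc, wdepth)[0])
    else:
        r = float("nan")
    return CoverageTrack(genome.record.id, depth, window, wdepth, wgc, r)


@dataclass
class OriginReport:
    total: int
    assigned: dict[str, int]
    ambiguous: int
    unassigned: int

    @property
    def fractions(self) -> dict[str, float]:
        return {g: n / self.total for g, n in self.assigned.items()}


def origin_fractions_from_counts(total: int, assigned: dict[str, int],
                                 ambiguous: int = 0) -> OriginReport:
    """Build the origin report directly from per-genome read counts."""
    unassigned = total - sum(assigned.values()) - ambiguous
    return OriginReport(total, dict(assigned), ambiguous, unassigned)


def read_origin_fractions(reads, genomes: dict[str, GenomeSequence],
                          k: int = 17, min_identity: float = 0.95,
                          min_read_fraction: float = 0.85) -> OriginReport:
    """Assign each read to the genome of its best qualifying placement.

    Equal best scores across genomes are counted ambiguous; reads with no
    qualifying placement anywhere are unassigned.
    """
    if not genomes:
        raise ValueError("at least one labelled genome required")
    max_len = max((len(r.residues) for r in reads), default=100)
    indexes = {label: ReadIndex(g, k, extension=max_len + 16)
               for label, g in genomes.items()}
    assigned = {label: 0 for label in genomes}
    ambiguous = unassigned = 0
    for read in reads:
        best_score, best_labels = None, []
        for label, idx in indexes.items():
            alns = map_read(read, idx, min_identity, min_read_fraction)
            if alns:
                sc = alns[0].score
                if best_score is None or sc > best_score:
                    best_score, best_labels = sc, [label]
                elif sc == best_score:
                    best_labels.append(label)
        if best_score is None:
            unassigned += 1
        elif len(best_labels) > 1:
            ambiguous += 1
        else:
            assigned[best_labels[0]] += 1
    return OriginReport(len(reads), assigned, ambiguous, unassigned)


# ---------------------------------------------------------------------------
# export


def write_alignment_tsv(alignments, path) -> None:
    with open(path, "w") as fh:
        fh.write("read\ttarget\tstart\tend\tstrand\tidentity\tread_fraction\t"
                 "aligned_length\tscore\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.target_id}\t{a.interval.start}\t"
                     f"{a.interval.end}\t{a.strand}\t{a.identity:.4f}\t"
                     f"{a.read_fraction:.4f}\t{a.aligned_length}\t{a.score}\n")


def write_sam(alignments, reads, genome: GenomeSequence, path) -> None:
    """Minimal SAM export (QNAME, FLAG, RNAME, POS, MAPQ=255, CIGAR, SEQ)."""
    seqs = {r.id: r.residues for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{genome.record.id}\tLN:{len(genome)}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            seq = seqs.get(a.read_id, "*")
            if seq != "*" and a.strand == "-":
                seq = revcomp(seq)
            cigar = a.cigar.replace("=", "M").replace("X", "M") if a.cigar else "*"
            fh.write(f"{a.read_id}\t{flag}\t{a.target_id}\t{a.interval.start + 1}"
                     f"\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n")
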