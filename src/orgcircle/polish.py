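"""Homopolymer polishing from accurate short-read pileups.

Pyrosequencing misestimates the length of single-base runs, so runs of >= 5 nt
in a draft assembly are re-measured from short reads: every qualifying read
covering a run votes with the run length it observed, and a strict majority
(> 50% of qualified votes) for a different length rewrites the run.  A vote
qualifies only when every base of the read's run plus one flanking base on
each side meets the quality threshold — local quality is what certifies the
observed run length.  Corrections shift downstream coordinates; an internal
edit map projects polished-genome positions back onto the draft so votes stay
anchored to the original alignments, and detection is re-run to a fixpoint in
case edits merge adjacent runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maplite import Alignment, _columns_from_cigar
from .seqio import GenomeSequence, Interval, SequenceRecord, revcomp
from .synthio import find_runs


@dataclass(frozen=True)
class HomopolymerSite:
    start: int
    base: str
    length: int  # reference run length


@dataclass
class CorrectionRecord:
    site: HomopolymerSite  # coordinates on the draft at first detection
    votes: dict[int, int]
    decision: str  # unchanged / corrected
    corrected_length: int
    supporting_reads: int
    in_coding: bool = False
    excluded: bool = False


def find_homopolymers(genome: GenomeSequence, min_length: int = 5) -> list[HomopolymerSite]:
    """All maximal single-base runs >= min_length (origin-spanning included)."""
    circular = genome.topology == "circular"
    return [HomopolymerSite(s, b, l)
            for s, b, l in find_runs(genome.seq, min_length, circular=circular)]


def _observed_run(aln: Alignment, read, base: str, lo: int, hi: int,
                  genome_length: int, min_quality: int) -> int | None:
    """Observed run length of ``base`` between draft coordinates [lo, hi).

    ``lo``/``hi`` bound the run plus one flanking base each side (hi may
    exceed the genome length for origin-spanning runs).  Returns None when the
    read does not fully span the window or any base in it is below quality.
    """
    t0 = aln.interval.start
    t1 = t0 + aln.aligned_length
    w_lo, w_hi = lo, hi
    if w_lo < t0 and w_lo + genome_length >= t0:  # alignment is unwrapped past L
        w_lo += genome_length
        w_hi += genome_length
    if not (t0 <= w_lo and w_hi <= t1) or not aln.cigar:
        return None
    seq = read.residues if aln.strand == "+" else revcomp(read.residues)
    quals = read.qualities
    if quals is not None and aln.strand == "-":
        quals = quals[::-1]
    q0 = aln.read_start if aln.strand == "+" else len(seq) - aln.read_end
    cols = _columns_from_cigar(seq, "", q0, t0, aln.cigar)
    q_positions = [q for op, q, t in cols
                   if (op in ("=", "X") and w_lo <= t < w_hi)
                   or (op == "I" and w_lo < t <= w_hi - 1)]
    if not q_positions:
        return None
    q_lo, q_hi = min(q_positions), max(q_positions) + 1
    if quals is not None and any(qv < min_quality for qv in quals[q_lo:q_hi]):
        return None
    window = seq[q_lo:q_hi]
    best = cur = 0
    for ch in window:
        cur = cur + 1 if ch == base else 0
        best = max(best, cur)
    return best


def correct_homopolymers(genome: GenomeSequence, alignments: list[Alignment],
                         reads, min_quality: int = 28, min_length: int = 5,
                         min_votes: int = 3,
                         exclusion_intervals: tuple[Interval, ...] = (),
                         coding_intervals: tuple[Interval, ...] = (),
                         max_passes: int = 5,
                         ) -> tuple[GenomeSequence, list[CorrectionRecord]]:
    """Majority-vote homopolymer correction; returns (corrected genome, records).

    Each pass detects runs on the current sequence, collects qualified votes
    per run (projected back to draft coordinates through the edit map),
    applies every strict-majority rewrite right-to-left, then re-detects;
    passes repeat until no edit is made or the cycle guard trips.
    """
    reads_by_id = {r.id: r for r in reads}
    by_start = sorted(alignments, key=lambda a: a.interval.start)
    L0 = len(genome)

    def votes_for(base: str, lo_orig: int, hi_orig: int) -> tuple[dict[int, int], int]:
        votes: dict[int, int] = {}
        n = 0
        for a in by_start:
            read = reads_by_id.get(a.read_id)
            if read is None:
                continue
            obs = _observed_run(a, read, base, lo_orig, hi_orig, L0, min_quality)
            if obs is not None:
                votes[obs] = votes.get(obs, 0) + 1
                n += 1
        return votes, n

    def overlaps(site: HomopolymerSite, intervals, L: int) -> bool:
        pts = (site.start, (site.start + site.length - 1) % L)
        return any(iv.contains(p) for iv in intervals for p in pts)

    current = genome
    orig_of = np.arange(L0)  # draft coordinate of every current base
    records: dict[int, CorrectionRecord] = {}  # keyed by draft left-flank coord

    for _pass in range(max_passes):
        L = len(current)
        sites = find_homopolymers(current, min_length)
        edits = []
        for site in sites:
            left_orig = int(orig_of[(site.start - 1) % L])
            right_orig = int(orig_of[(site.start + site.length) % L])
            lo, hi = left_orig, right_orig + 1
            if hi <= lo:
                hi += L0
            votes, n_support = votes_for(site.base, lo, hi)
            is_excluded = overlaps(site, exclusion_intervals, L)
            decision, new_len = "unchanged", site.length
            total = sum(votes.values())
            if not is_excluded and total >= min_votes:
                top_len, top_n = max(votes.items(),
                                     key=lambda kv: (kv[1], -abs(kv[0] - site.length)))
                if top_len != site.length and top_n * 2 > total:
                    decision, new_len = "corrected", top_len
            rec = records.get(left_orig)
            if rec is None:
                records[left_orig] = CorrectionRecord(
                    site, votes, decision, new_len, n_support,
                    in_coding=overlaps(site, coding_intervals, L),
                    excluded=is_excluded,
                )
            elif decision == "corrected":
                rec.decision = "corrected"
                rec.corrected_length = new_len
                rec.votes = votes
                rec.supporting_reads = n_support
            if decision == "corrected":
                edits.append((site, new_len))
        if not edits:
            break
        seq = current.seq
        idx = orig_of
        for site, new_len in sorted(edits, key=lambda e: -e[0].start):
            s, n_old = site.start, site.length
            if s + n_old <= len(seq):
                keep = min(n_old, new_len)
                run_idx = idx[s : s + keep]
                pad = np.full(max(0, new_len - n_old), run_idx[-1] if keep else idx[s])
                seq = seq[:s] + site.base * new_len + seq[s + n_old :]
                idx = np.concatenate([idx[:s], run_idx, pad, idx[s + n_old :]])
            else:  # origin-spanning: rotate so the run is internal, edit, rotate back
                rot = (s + n_old) % len(seq)
                rseq = seq[rot:] + seq[:rot]
                ridx = np.concatenate([idx[rot:], idx[:rot]])
                rs = s - rot
                keep = min(n_old, new_len)
                run_idx = ridx[rs : rs + keep]
                pad = np.full(max(0, new_len - n_old), run_idx[-1] if keep else ridx[rs])
                rseq = rseq[:rs] + site.base * new_len + rseq[rs + n_old :]
                ridx = np.concatenate([ridx[:rs], run_idx, pad, ridx[rs + n_old :]])
                seq = rseq[-rot:] + rseq[:-rot] if rot else rseq
                idx = np.concatenate([ridx[-rot:], ridx[:-rot]]) if rot else ridx
        orig_of = idx
        current = GenomeSequence(SequenceRecord(genome.record.id, seq,
                                                genome.record.description),
                                 genome.topology)
    return current, sorted(records.values(), key=lambda r: r.site.start)


def error_report(records: list[CorrectionRecord]) -> pd.DataFrame:
    """Correction summary by coding status (the finished-genome error table)."""
    rows = {klass: dict(sites=0, cum_length=0, corrected_sites=0, corrected_length=0)
            for klass in ("coding", "non-coding", "total")}
    for rec in records:
        err = abs(rec.corrected_length - rec.site.length) \
            if rec.decision == "corrected" else 0
        for klass in ("total", "coding" if rec.in_coding else "non-coding"):
            rows[klass]["sites"] += 1
            rows[klass]["cum_length"] += rec.site.length
            if rec.decision == "corrected":
                rows[klass]["corrected_sites"] += 1
                rows[klass]["corrected_length"] += err
    return summarize_error_counts(rows)


def summarize_error_counts(rows: dict[str, dict]) -> pd.DataFrame:
    """Attach the percent-error column: 100 x corrected length / run length."""
    df = pd.DataFrame(rows).T
    df["percent_error"] = (100.0 * df["corrected_length"] / df["cum_length"]).where(
        df["cum_length"] > 0, 0.0
    )
    df.index.name = "sequence"
    return df


def write_correction_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tbase\tref_length\tdecision\tcorrected_length\t"
                 "supporting_reads\tvotes\tin_coding\texcluded\n")
        for r in records:
            votes = ",".join(f"{k}:{v}" for k, v in sorted(r.votes.items()))
            fh.write(f"{r.site.start}\t{r.site.base}\t{r.site.length}\t{r.decision}\t"
                     f"{r.corrected_length}\t{r.supporting_reads}\t{votes}\t"
                     f"{int(r.in_coding)}\t{int(r.excluded)}\n")
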