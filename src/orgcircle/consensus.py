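"""Consensus of replicate assemblies of one circular genome.

Independent assemblies of the same circle differ in rotation, strand, small
masked gaps ('N' runs) and the occasional short indel.  Rather than a general
multiple alignment, the consensus is built the way near-identical replicates
allow: replicates are rotated/flipped onto a shared anchor, k-mers unique
within every replicate and shared by all are chained colinearly as anchors,
and the blocks between anchors are column-voted (pairwise-aligning a block to
the first replicate carrying sequence when block lengths differ).  Masked
positions do not vote; when every replicate is masked the column stays 'N';
unresolved ties emit IUPAC ambiguity codes and are listed in the column
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .seqio import GenomeSequence, SequenceRecord, revcomp

IUPAC_FROM_BASES = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class ConsensusColumn:
    position: int
    votes: dict[str, int]
    decision: str


class ReplicateError(ValueError):
    pass


def normalize_replicates(replicates: list[GenomeSequence],
                         anchor: str) -> list[GenomeSequence]:
    """Rotate/flip every replicate so the anchor starts at position 0 forward.

    The anchor must occur exactly once per replicate across both strands.
    """
    anchor = anchor.upper()
    out = []
    for rep in replicates:
        doubled = rep.seq + rep.seq[: len(anchor) - 1]
        rc = revcomp(rep.seq)
        doubled_rc = rc + rc[: len(anchor) - 1]
        hits_f = _find_all(doubled, anchor)
        hits_r = _find_all(doubled_rc, anchor)
        total = len(hits_f) + len(hits_r)
        if total == 0:
            raise ReplicateError(f"anchor absent from replicate {rep.record.id}")
        if total > 1:
            raise ReplicateError(
                f"anchor occurs {total} times in replicate {rep.record.id}"
            )
        if hits_f:
            pos = hits_f[0]
            seq = rep.seq[pos:] + rep.seq[:pos]
        else:
            pos = hits_r[0]
            seq = rc[pos:] + rc[:pos]
        out.append(GenomeSequence(SequenceRecord(rep.record.id, seq,
                                                 rep.record.description),
                                  "circular"))
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        counts[km] = counts.get(km, 0) + 1
        pos[km] = i
    return {km: p for km, p in pos.items() if counts[km] == 1 and "N" not in km}


def _vote_column(bases: list[str]) -> tuple[str, dict[str, int]]:
    votes: dict[str, int] = {}
    for b in bases:
        if b not in "N-":
            votes[b] = votes.get(b, 0) + 1
    if not votes:
        return "N", votes
    top = max(votes.values())
    winners = frozenset(b for b, n in votes.items() if n == top)
    if len(winners) == 1:
        return next(iter(winners)), votes
    if "-" in winners:
        winners = winners - {"-"}
    return IUPAC_FROM_BASES.get(frozenset(winners), "N"), votes


def _align_block(block: str, ref_block: str) -> str:
    """Project a block onto a reference block's columns ('-' where ref has gaps)."""
    if block == ref_block:
        return block
    res = edlib.align(block, ref_block, mode="NW", task="path")
    out = []
    q = t = 0
    from .maplite import _expand_cigar

    for n, op in _expand_cigar(res["cigar"]):
        if op in ("=", "X"):
            out.append(block[q : q + n]); q += n; t += n
        elif op == "I":  # extra block bases: no reference column, dropped
            q += n
        elif op == "D":  # reference columns absent from the block
            out.append("-" * n); t += n
    return "".join(out)


def build_consensus(replicates: list[GenomeSequence], k: int = 21,
                    min_identity: float = 0.95,
                    ) -> tuple[GenomeSequence, list[ConsensusColumn]]:
    """Consensus of normalized replicates; returns (consensus, ambiguous columns).

    Requires >= 2 replicates.  The anchor chain (k-mers unique in every
    replicate, shared by all, colinear) must cover at least half the median
    replicate length, otherwise the replicates are considered too divergent.
    """
    if len(replicates) < 2:
        raise ReplicateError("need at least two replicates")
    seqs = [r.seq for r in replicates]
    # pairwise identity guard (masked 'N' positions treated as matching)
    eq = [("N", b) for b in "ACGTN"] + [(b, "N") for b in "ACGT"]
    for i, s in enumerate(seqs[1:], 1):
        d = edlib.align(s, seqs[0], mode="NW", task="distance",
                        additionalEqualities=eq)["editDistance"]
        ident = 1.0 - d / max(len(s), len(seqs[0]))
        if ident < min_identity:
            raise ReplicateError(
                f"replicate {replicates[i].record.id} only {ident:.1%} identical "
                f"to {replicates[0].record.id}; not replicates of one genome"
            )
    uniq = [_unique_kmers(s, k) for s in seqs]
    shared = set(uniq[0])
    for u in uniq[1:]:
        shared &= set(u)
    # colinear chain: longest increasing run over all replicates' positions
    anchors = sorted(shared, key=lambda km: uniq[0][km])
    chain = []
    last = [-k] * len(seqs)
    for km in anchors:
        ps = [u[km] for u in uniq]
        if all(p >= l + k for p, l in zip(ps, last)):  # colinear, non-overlapping
            chain.append(ps)
            last = ps
    lengths = sorted(len(s) for s in seqs)
    median_len = lengths[len(lengths) // 2]
    if not chain or (chain[-1][0] + k - chain[0][0]) < 0.5 * median_len:
        raise ReplicateError(
            "anchor chain covers <50% of the median replicate; replicates "
            "too divergent for column consensus"
        )

    pieces: list[str] = []
    ambiguous: list[ConsensusColumn] = []

    def vote_block(blocks: list[str], offset: int) -> int:
        ref = next((b for b in blocks if b.strip("N")), blocks[0])
        projected = []
        for b in blocks:
            if len(b) == len(ref):
                projected.append(b)
            elif b.strip("N") == "":
                projected.append("N" * len(ref))
            else:
                projected.append(_align_block(b, ref))
        for j in range(len(ref)):
            col = [p[j] for p in projected]
            base, votes = _vote_column(col)
            pieces.append(base)
            if base not in "ACGT":
                ambiguous.append(ConsensusColumn(offset + j, votes, base))
        return len(ref)

    # leading blocks before the first anchor, the anchors themselves, the
    # inter-anchor blocks, and the circular tail after the last anchor
    n_anchors = len(chain)
    pos_out = 0
    for i in range(n_anchors):
        starts = chain[i]
        # anchor columns: identical by construction
        pieces.append(seqs[0][starts[0] : starts[0] + k])
        pos_out += k
        nxt = chain[(i + 1) % n_anchors]
        blocks = []
        for s, seq, st in zip(starts, seqs, nxt):
            a = s + k
            b = st if i + 1 < n_anchors else st + len(seq)
            blocks.append((seq + seq)[a:b])
        if any(blocks):
            pos_out += vote_block(blocks, pos_out)
    consensus = "".join(pieces)
    rec = GenomeSequence(SequenceRecord("consensus", consensus), "circular")
    return rec, ambiguous


def write_column_report(columns: list[ConsensusColumn], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tvotes\tdecision\n")
        for c in columns:
            votes = ",".join(f"{b}:{n}" for b, n in sorted(c.votes.items()))
            fh.write(f"{c.position}\t{votes}\t{c.decision}\n")
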