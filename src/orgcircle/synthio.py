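"""Deterministic simulation of circular organelle genomes and read sets.

The generator emulates the structure of a plant mitochondrial master circle:
single-copy regions separated by large repeats (direct and inverted), with
homopolymer runs of the kind pyrosequencing misestimates.  The default layout
carries five single-copy regions (A-E) and four large repeats (R1-R4), with
R1 sitting between R2 and R3 so the three form a direct super-repeat block,
and the second copy of R4 inverted — the configuration that admits exactly two
master-circle conformations (inversion isomers across R4) while direct-repeat
recombination yields sub-circles.

Every generator takes an explicit seed and is byte-deterministic under it.
Truth tables are returned as pandas DataFrames and are sufficient to score
mapping, repeat recovery and polishing without external input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import GenomeSequence, SequenceRecord, revcomp

BASES = "ACGT"


@dataclass(frozen=True)
class RepeatDef:
    label: str
    length: int


@dataclass
class GenomeSpec:
    """Layout of a circular genome as an ordered ring of oriented blocks.

    ``layout`` lists (label, strand) clockwise around the circle; labels refer
    to ``segment_lengths`` (single-copy, each used once) or ``repeat_lengths``
    (used as many times as they appear).  ``homopolymer_runs`` are run lengths
    (>=5) planted at random positions inside single-copy segments.
    """

    segment_lengths: dict[str, int]
    repeat_lengths: dict[str, int]
    layout: tuple[tuple[str, str], ...]
    gc: float = 0.45
    homopolymer_runs: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.layout]
        for lab in self.segment_lengths:
            if labels.count(lab) != 1:
                raise ValueError(f"single-copy segment {lab} must appear exactly once")
        for lab in labels:
            if lab not in self.segment_lengths and lab not in self.repeat_lengths:
                raise ValueError(f"layout block {lab} is undefined")
        for lab, n in self.repeat_lengths.items():
            if labels.count(lab) < 1:
                raise ValueError(f"repeat {lab} never placed")
        if any(r < 5 for r in self.homopolymer_runs):
            raise ValueError("homopolymer runs must be >= 5 nt")

    def copy_counts(self) -> dict[str, int]:
        labels = [lab for lab, _ in self.layout]
        return {lab: labels.count(lab) for lab in dict.fromkeys(labels)}

    @property
    def genome_length(self) -> int:
        return sum(self.block_length(lab) for lab, _ in self.layout)

    def block_length(self, label: str) -> int:
        if label in self.segment_lengths:
            return self.segment_lengths[label]
        return self.repeat_lengths[label]


def plant_mito_spec(scale: float = 1.0, seed: int = 0,
                    homopolymer_runs: tuple[int, ...] = (5, 6, 7, 5, 8, 6, 5, 9, 6, 5),
                    ) -> GenomeSpec:
    """Default study layout: 5 single-copy regions, 4 large repeats.

    R2-R1-R3 forms a direct super-repeat present twice; R4 is present twice
    with the second copy inverted.  ``scale`` shrinks all block lengths for
    desk-scale fixtures.
    """
    seg = {lab: int(n * scale)
           for lab, n in zip("ABCDE", (6000, 5000, 4000, 5500, 4500))}
    rep = {f"R{i}": int(n * scale)
           for i, n in zip((1, 2, 3, 4), (3000, 2000, 2500, 1500))}
    layout = (
        ("A", "+"), ("R2", "+"), ("R1", "+"), ("R3", "+"),
        ("B", "+"), ("R4", "+"), ("C", "+"), ("R4", "-"),
        ("D", "+"), ("R2", "+"), ("R1", "+"), ("R3", "+"), ("E", "+"),
    )
    return GenomeSpec(seg, rep, layout, gc=0.45,
                      homopolymer_runs=homopolymer_runs, seed=seed)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _plant_homopolymers(rng: np.random.Generator, blocks: dict[str, str],
                        single_labels: list[str],
                        runs: tuple[int, ...]) -> None:
    """Overwrite random stretches inside single-copy blocks with base runs."""
    for run_len in runs:
        lab = single_labels[rng.integers(len(single_labels))]
        seq = blocks[lab]
        # keep one flanking base inside the block so the run stays maximal
        pos = int(rng.integers(1, len(seq) - run_len - 1))
        base = BASES[rng.integers(4)]
        left = seq[pos - 1]
        right = seq[pos + run_len]
        if left == base or right == base:
            # shift flanks to a different base so the planted run is maximal
            other = next(b for b in BASES if b != base)
            seq = seq[: pos - 1] + other + base * run_len + other + seq[pos + run_len + 1 :]
        else:
            seq = seq[:pos] + base * run_len + seq[pos + run_len :]
        blocks[lab] = seq


def find_runs(seq: str, min_len: int = 5, circular: bool = True) -> list[tuple[int, str, int]]:
    """Maximal single-base runs >= min_len as (start, base, length).

    On circular sequences a run spanning the origin is reported once with its
    start near the end of the sequence.
    """
    n = len(seq)
    if n == 0:
        return []
    runs: list[list] = []  # [start, length, base]
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        runs.append([i, j - i, seq[i]])
        i = j
    if circular and len(runs) > 1 and runs[0][2] == runs[-1][2]:
        first = runs.pop(0)
        runs[-1][1] += first[1]  # wraps the origin; reported from its true start
    return [(s, b, l) for s, l, b in runs if l >= min_len]


def build_genome(spec: GenomeSpec) -> tuple[GenomeSequence, dict]:
    """Realize a GenomeSpec into a circular sequence plus truth tables.

    Truth is a dict of DataFrames/lists: ``blocks`` (label, copy, start, end,
    strand), ``repeat_pairs`` (label, coords of both copies, orientation),
    ``super_blocks`` (merged adjacent-repeat spans), and ``homopolymers``.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = {}
    for lab in list(spec.segment_lengths) + list(spec.repeat_lengths):
        blocks[lab] = _random_dna(rng, spec.block_length(lab), spec.gc)
    _plant_homopolymers(rng, blocks, list(spec.segment_lengths), spec.homopolymer_runs)

    parts: list[str] = []
    rows = []
    pos = 0
    copy_idx: dict[str, int] = {}
    for lab, strand in spec.layout:
        seq = blocks[lab] if strand == "+" else revcomp(blocks[lab])
        k = copy_idx.get(lab, 0)
        copy_idx[lab] = k + 1
        rows.append(dict(label=lab, copy=k, start=pos, end=pos + len(seq),
                         strand=strand,
                         kind="repeat" if lab in spec.repeat_lengths else "single"))
        parts.append(seq)
        pos += len(seq)
    genome_seq = "".join(parts)
    block_df = pd.DataFrame(rows)

    pair_rows = []
    for lab in spec.repeat_lengths:
        occ = block_df[block_df.label == lab]
        occs = occ.to_dict("records")
        for i in range(len(occs)):
            for j in range(i + 1, len(occs)):
                a, b = occs[i], occs[j]
                pair_rows.append(dict(
                    label=lab,
                    start1=a["start"], end1=a["end"], strand1=a["strand"],
                    start2=b["start"], end2=b["end"], strand2=b["strand"],
                    orientation="direct" if a["strand"] == b["strand"] else "inverted",
                ))
    repeat_pairs = pd.DataFrame(pair_rows)

    # merged blocks of layout-adjacent repeats (super-repeats)
    super_rows = []
    cur = None
    for row in block_df.itertuples():
        if row.kind == "repeat":
            if cur is None:
                cur = [row.start, row.end, [row.label]]
            else:
                cur[1] = row.end
                cur[2].append(row.label)
        elif cur is not None:
            super_rows.append(dict(start=cur[0], end=cur[1], labels="+".join(cur[2])))
            cur = None
    if cur is not None:
        super_rows.append(dict(start=cur[0], end=cur[1], labels="+".join(cur[2])))
    super_blocks = pd.DataFrame(super_rows)

    hp = pd.DataFrame(find_runs(genome_seq, 5, circular=True),
                      columns=["start", "base", "length"])

    genome = GenomeSequence(SequenceRecord("synthetic_circle", genome_seq), "circular")
    truth = dict(blocks=block_df, repeat_pairs=repeat_pairs,
                 super_blocks=super_blocks, homopolymers=hp, spec=spec)
    return genome, truth


def distort_homopolymers(genome: GenomeSequence, rate: float = 0.8,
                         min_run: int = 5, seed: int = 0,
                         ) -> tuple[GenomeSequence, pd.DataFrame]:
    """Plant +-1 length errors at homopolymer runs (a pyrosequencing-like draft).

    Each maximal run >= ``min_run`` is distorted with probability ``rate``.
    Runs at exactly ``min_run`` are only lengthened — a shortened run would
    drop below the detection threshold and be invisible to run-directed
    correction, which is not the error mode being emulated.  Returns the
    distorted genome and a table of planted errors in draft coordinates.
    """
    rng = np.random.default_rng(seed)
    runs = sorted(find_runs(genome.seq, min_run, circular=genome.topology == "circular"),
                  key=lambda r: -r[0])
    seq = genome.seq
    rows = []
    for start, base, length in runs:
        if start + length > len(seq):
            continue  # origin-spanning runs left undistorted
        if rng.random() >= rate:
            continue
        delta = 1 if (length == min_run or rng.random() < 0.5) else -1
        seq = seq[:start] + base * (length + delta) + seq[start + length :]
        rows.append(dict(start=start, base=base, true_length=length, delta=delta))
    draft = GenomeSequence(SequenceRecord(genome.record.id + "_draft", seq),
                           genome.topology)
    shift = 0
    table = pd.DataFrame(sorted(rows, key=lambda r: r["start"]),
                         columns=["start", "base", "true_length", "delta"])
    if len(table):
        # convert to draft coordinates (edits applied right-to-left upstream)
        offsets = np.concatenate([[0], np.cumsum(table["delta"].to_numpy())[:-1]])
        table["draft_start"] = table["start"] + offsets
    return draft, table


# ---------------------------------------------------------------------------
# truth contigs and contig graph


def emit_truth_contigs(genome: GenomeSequence, truth: dict,
                       base_depth: float = 20.0, base_support: int = 25,
                       depth_noise_sd: float = 0.0, seed: int = 0,
                       ) -> tuple[list[SequenceRecord], str]:
    """Contigs + contig-graph text an assembler would have produced.

    One contig per single-copy segment and one per distinct repeat; repeat
    depth scales with copy count.  Connections carry read-support counts; the
    same junction occurring at several layout positions is merged with summed
    support.  Returns (contig records, graph file text).
    """
    spec: GenomeSpec = truth["spec"]
    rng = np.random.default_rng(seed)
    block_df = truth["blocks"]
    counts = spec.copy_counts()

    contigs = []
    seen = set()
    for row in block_df.itertuples():
        if row.label in seen:
            continue
        seen.add(row.label)
        seq = genome.seq[row.start:row.end]
        if row.strand == "-":
            seq = revcomp(seq)
        contigs.append(SequenceRecord(row.label, seq))

    depth = {}
    for lab, copies in counts.items():
        d = base_depth * copies
        if depth_noise_sd > 0:
            d += rng.normal(0.0, depth_noise_sd * base_depth)
        depth[lab] = max(d, 0.1)

    # junctions between consecutive layout blocks (circular)
    conn: dict[frozenset, int] = {}
    layout = spec.layout
    for i in range(len(layout)):
        (la, sa), (lb, sb) = layout[i], layout[(i + 1) % len(layout)]
        side_a = "R" if sa == "+" else "L"
        side_b = "L" if sb == "+" else "R"
        key = frozenset([(la, side_a), (lb, side_b)]) if (la, side_a) != (lb, side_b) \
            else frozenset([(la, side_a)])
        support = base_support + int(rng.integers(0, 6))
        conn[key] = conn.get(key, 0) + support

    lines = ["# synthetic contig graph"]
    for rec in contigs:
        lines.append(f"C\t{rec.id}\t{len(rec)}\t{depth[rec.id]:.2f}")
    for key in sorted(conn, key=lambda k: sorted(k)):
        ends = sorted(key)
        if len(ends) == 1:  # self-junction (same contig end to itself)
            (la, side_a) = ends[0]
            lb, side_b = la, side_a
        else:
            (la, side_a), (lb, side_b) = ends
        lines.append(f"L\t{la}\t{side_a}\t{lb}\t{side_b}\t{conn[key]}")
    return contigs, "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# read simulators


def simulate_long_reads(genome: GenomeSequence, n: int,
                        length_mean: float = 380.0, length_sd: float = 60.0,
                        homopolymer_error_rate: float = 0.1,
                        min_run: int = 5, seed: int = 0,
                        ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Long shotgun reads with +-1 nt homopolymer length errors.

    Reads start uniformly on the circle; every maximal run >= ``min_run``
    fully inside a read is independently lengthened or shortened by one base
    with probability ``homopolymer_error_rate`` (equal odds each way).
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    reads, rows = [], []
    for i in range(n):
        rlen = max(50, int(rng.normal(length_mean, length_sd)))
        rlen = min(rlen, L)
        start = int(rng.integers(L))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome.fetch(start, start + rlen)
        if strand == "-":
            seq = revcomp(seq)
        n_err = 0
        for run_start, base, run_len in reversed(find_runs(seq, min_run, circular=False)):
            if run_start == 0 or run_start + run_len >= len(seq):
                continue  # truncated run: true length not observable
            if rng.random() < homopolymer_error_rate:
                delta = 1 if rng.random() < 0.5 else -1
                seq = seq[:run_start] + base * (run_len + delta) + seq[run_start + run_len:]
                n_err += 1
        reads.append(SequenceRecord(f"lr{i}", seq))
        rows.append(dict(read=f"lr{i}", start=start, strand=strand,
                         true_length=rlen, hp_errors=n_err))
    return reads, pd.DataFrame(rows)


def window_gc(seq: str, window: int) -> np.ndarray:
    """GC fraction of circular windows [i, i+window) for every start i."""
    arr = np.frombuffer((seq + seq[:window]).encode(), dtype=np.uint8)
    isgc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(isgc)])
    return (cum[window:] - cum[:-window])[: len(seq)] / window


def simulate_short_reads(genome: GenomeSequence, coverage: float,
                         read_length: int = 100,
                         substitution_rate: float = 0.001,
                         gc_bias: float = 0.0,
                         quality_mean: float = 38.0, quality_sd: float = 2.0,
                         seed: int = 0,
                         ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Accurate short reads with per-base qualities and optional GC bias.

    Start positions are drawn with weight exp(-gc_bias * GC(window)) so a
    positive coefficient depresses coverage of GC-rich windows, emulating the
    coverage dips short-read platforms show there.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    n = int(round(coverage * L / read_length))
    if gc_bias != 0.0:
        w = np.exp(-gc_bias * window_gc(genome.seq, read_length))
        p = w / w.sum()
        starts = rng.choice(L, size=n, p=p)
    else:
        starts = rng.integers(0, L, size=n)
    strands = rng.random(n) < 0.5
    reads, rows = [], []
    base_arr = np.array(list(BASES))
    for i in range(n):
        start = int(starts[i])
        seq = genome.fetch(start, start + read_length)
        strand = "+" if strands[i] else "-"
        if strand == "-":
            seq = revcomp(seq)
        nsub = 0
        if substitution_rate > 0:
            mask = rng.random(read_length) < substitution_rate
            if mask.any():
                chars = np.array(list(seq))
                for j in np.nonzero(mask)[0]:
                    choices = [b for b in BASES if b != chars[j]]
                    chars[j] = choices[rng.integers(3)]
                    nsub += 1
                seq = "".join(chars)
        quals = np.clip(rng.normal(quality_mean, quality_sd, read_length),
                        2, 41).astype(int).tolist()
        reads.append(SequenceRecord(f"sr{i}", seq, qualities=quals))
        rows.append(dict(read=f"sr{i}", start=start, strand=strand, subs=nsub))
    return reads, pd.DataFrame(rows)


def simulate_paired_ends(genome: GenomeSequence, n: int,
                         insert_mean: float = 3000.0, insert_sd: float = 300.0,
                         end_length: int = 150, seed: int = 0,
                         ) -> tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Inward-facing read pairs at a drawn insert distance on the circle."""
    if insert_mean <= 2 * end_length:
        raise ValueError("insert mean must exceed twice the end length")
    rng = np.random.default_rng(seed)
    L = len(genome)
    fwd, rev, rows = [], [], []
    for i in range(n):
        insert = max(2 * end_length, int(round(rng.normal(insert_mean, insert_sd))))
        insert = min(insert, L)
        start = int(rng.integers(L))
        left = genome.fetch(start, start + end_length)
        right = revcomp(genome.fetch(start + insert - end_length, start + insert))
        q = [40] * end_length
        fwd.append(SequenceRecord(f"pe{i}/1", left, qualities=list(q)))
        rev.append(SequenceRecord(f"pe{i}/2", right, qualities=list(q)))
        rows.append(dict(pair=f"pe{i}", start=start, insert=insert,
                         mate_start=(start + insert - end_length) % L))
    return fwd, rev, pd.DataFrame(rows)
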