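"""Sequence and interval I/O with the coordinate conventions used package-wide.

Internal coordinates are 0-based half-open everywhere; human-readable report
files use 1-based inclusive positions and are labelled as such.  Circular
features that span the origin are stored with ``start > end`` and an explicit
topology flag on the parent sequence; BED serialisation splits them into two
lines sharing a name, because BED has no circular convention.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA sequence, optionally with Phred-scale base qualities."""

    id: str
    residues: str
    description: str = ""
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise FormatError(
                f"record {self.id}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GenomeSequence:
    """A sequence plus its topology (circular genomes wrap coordinates)."""

    record: SequenceRecord
    topology: str = "circular"  # or "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def seq(self) -> str:
        return self.record.residues

    def __len__(self) -> int:
        return len(self.record.residues)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); on circular genomes end may wrap past L."""
        s = self.seq
        n = len(s)
        if self.topology == "linear":
            if not (0 <= start <= end <= n):
                raise ValueError(f"[{start}, {end}) outside linear sequence of {n}")
            return s[start:end]
        if end < start:
            raise ValueError("fetch requires end >= start (pass end > L to wrap)")
        span = end - start
        if span > n:
            raise ValueError("requested span longer than the circle")
        start %= n
        stop = start + span
        if stop <= n:
            return s[start:stop]
        return s[start:] + s[: stop - n]


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named target.

    On circular targets ``start > end`` denotes an origin-spanning feature.
    """

    target: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def length(self, target_length: int | None = None) -> int:
        if self.start <= self.end:
            return self.end - self.start
        if target_length is None:
            raise ValueError("origin-spanning interval needs the target length")
        return target_length - self.start + self.end

    def contains(self, pos: int) -> bool:
        if self.start <= self.end:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _validate_residues(rec: SequenceRecord, path, idx: int) -> None:
    bad = set(rec.residues) - IUPAC_DNA
    if bad:
        # report 1-based record number; FASTA line attribution is per-record
        raise FormatError(
            f"{path}: record #{idx + 1} ({rec.id}) contains non-IUPAC "
            f"characters {sorted(bad)}"
        )


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into SequenceRecords."""
    out: list[SequenceRecord] = []
    with _open(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fasta")):
            sr = SequenceRecord(rec.id, str(rec.seq), rec.description)
            _validate_residues(sr, path, i)
            out.append(sr)
    return out


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path) -> list[SequenceRecord]:
    """Read FASTQ (strictly Phred+33) into SequenceRecords with qualities."""
    out: list[SequenceRecord] = []
    with _open(path) as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
                sr = SequenceRecord(
                    rec.id, str(rec.seq), rec.description,
                    list(rec.letter_annotations["phred_quality"]),
                )
                _validate_residues(sr, path, i)
                out.append(sr)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            quals = rec.qualities
            if quals is None:
                quals = [40] * len(rec.residues)
            bio = SeqRecord(Seq(rec.residues), id=rec.id, description=rec.description)
            bio.letter_annotations["phred_quality"] = quals
            SeqIO.write(bio, fh, "fastq")


def write_bed(features: Sequence[Interval], path,
              target_lengths: dict[str, int] | None = None,
              names: Sequence[str] | None = None) -> None:
    """Write intervals as BED3+ (name column when provided).

    Origin-spanning intervals (start > end, circular target) are split into
    two lines sharing a name so standard BED tools can consume them.
    """
    target_lengths = target_lengths or {}
    with _open(path, "wt") as fh:
        for i, iv in enumerate(features):
            name = names[i] if names is not None else None
            if iv.start <= iv.end:
                cols = [iv.target, str(iv.start), str(iv.end)]
                if name is not None:
                    cols.append(name)
                fh.write("\t".join(cols) + "\n")
            else:
                n = target_lengths.get(iv.target)
                if n is None:
                    raise ValueError(
                        f"origin-spanning interval on {iv.target} needs its length"
                    )
                shared = name if name is not None else f"wrap{i}"
                fh.write(f"{iv.target}\t{iv.start}\t{n}\t{shared}\n")
                fh.write(f"{iv.target}\t0\t{iv.end}\t{shared}\n")


def read_bed(path) -> list[Interval]:
    out: list[Interval] = []
    with _open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >=3 columns")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            try:
                out.append(Interval(parts[0], int(parts[1]), int(parts[2]), strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return out


def read_genbank_sequence(path) -> list[SequenceRecord]:
    """Read sequences (id + residues only) from a GenBank flat file."""
    with _open(path) as fh:
        return [SequenceRecord(r.id, str(r.seq), r.description)
                for r in SeqIO.parse(fh, "genbank")]
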