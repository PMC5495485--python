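"""Sequence containers, coordinate conventions and FASTA/FASTQ I/O.

All coordinates in this package are 0-based, half-open.  Genomes are plain
nucleotide strings over {A, C, G, T, N}, upper-cased at ingestion; ``N``
never matches anything in anchoring or repeat detection.  Circular genomes
carry an ``origin_offset`` recording the rotation applied so that position 0
is the chosen replication origin (origin positions are a user input; they are
not predicted here).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

__all__ = [
    "GenomeRecord",
    "Interval",
    "reverse_complement",
    "rotate_circular",
    "load_genome",
    "load_genomes",
    "write_fasta",
    "iter_fastq",
    "write_fastq",
    "SequenceParseError",
]


class SequenceParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input or illegal characters."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of ``seq`` (A<->T, C<->G, N->N).

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    bad = set(seq.upper()) - ALPHABET
    if bad:
        raise SequenceParseError(
            f"illegal character(s) {sorted(bad)} in sequence"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval ``[start, end)`` with a strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence, optionally circular.

    ``origin_offset`` records the total rotation applied relative to the
    sequence as loaded, so rotating by ``origin_offset`` and then by
    ``length - origin_offset`` restores the original sequence.
    """

    id: str
    seq: str
    circular: bool = False
    origin_offset: int = 0

    def __post_init__(self):
        if not self.seq:
            raise SequenceParseError(f"record {self.id!r}: empty sequence")
        s = self.seq.upper()
        bad = set(s) - ALPHABET
        if bad:
            raise SequenceParseError(
                f"record {self.id!r}: illegal character(s) {sorted(bad)}"
            )
        object.__setattr__(self, "seq", s)
        if not 0 <= self.origin_offset < len(s):
            raise ValueError("origin_offset outside [0, length)")

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, iv: Interval) -> str:
        """Sequence of ``iv``; reverse-complemented if ``iv.strand == '-'``.

        On circular records ``end`` may exceed the length to denote
        wrap-around.
        """
        if iv.end <= len(self.seq):
            s = self.seq[iv.start : iv.end]
        elif self.circular:
            s = (self.seq + self.seq)[iv.start : iv.end]
        else:
            raise ValueError("interval beyond the end of a linear record")
        return reverse_complement(s) if iv.strand == "-" else s


def rotate_circular(g: GenomeRecord, new_origin: int) -> GenomeRecord:
    """Rotate a circular genome so that ``new_origin`` becomes position 0."""
    if not g.circular:
        raise ValueError(f"cannot rotate linear record {g.id!r}")
    n = len(g.seq)
    if not 0 <= new_origin < n:
        raise ValueError("new_origin outside [0, length)")
    return replace(
        g,
        seq=g.seq[new_origin:] + g.seq[:new_origin],
        origin_offset=(g.origin_offset + new_origin) % n,
    )


def _find_bad_line(path: str) -> str:
    """Locate the first FASTA body line with a character outside the alphabet."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(">"):
                continue
            if set(line.upper()) - ALPHABET:
                return f" (line {lineno}: {line[:40]!r})"
    return ""


def load_genomes(path: str, circular: bool = False) -> list[GenomeRecord]:
    """Load all records of a FASTA file as :class:`GenomeRecord` objects.

    Record ids are the FASTA headers up to the first whitespace; sequences
    are upper-cased.  Empty files, empty sequences and characters outside
    {A,C,G,T,N} raise :class:`SequenceParseError` naming the offending line.
    """
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        try:
            records.append(
                GenomeRecord(id=rec.id, seq=str(rec.seq), circular=circular)
            )
        except SequenceParseError as exc:
            raise SequenceParseError(f"{path}: {exc}{_find_bad_line(path)}") from None
    if not records:
        raise SequenceParseError(f"{path}: no FASTA records found")
    return records


def load_genome(path: str, circular: bool = False) -> GenomeRecord:
    """Load a FASTA file that must contain exactly one record."""
    records = load_genomes(path, circular=circular)
    if len(records) != 1:
        raise SequenceParseError(
            f"{path}: expected exactly one record, found {len(records)}"
        )
    return records[0]


def write_fasta(records, path: str, width: int = 70) -> None:
    """Write records as FASTA, upper-case, wrapped at ``width`` columns."""
    if isinstance(records, GenomeRecord):
        records = [records]
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def iter_fastq(path):
    """Yield ``(name, seq, qual)`` tuples from a FASTQ file (Phred+33)."""
    with open(path) as fh:
        for name, seq, qual in FastqGeneralIterator(fh):
            yield name, seq.upper(), qual


def write_fastq(reads, path: str) -> None:
    """Write ``(name, seq, qual)`` tuples as FASTQ (Phred+33)."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
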