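"""Sequence I/O primitives shared by every stage of the pipeline.

Reads are handled as 4-line FASTQ records with Phred+33 qualities (the
modern Illumina convention); Phred+64 input is supported through an explicit
``offset`` argument rather than auto-detection, so that trimming is
reproducible. Transcript sets are plain (optionally gzipped) FASTA.

Sequences are uppercased on read and restricted to the {A, C, G, T, N}
alphabet so that downstream hashing (duplicate removal, k-mer indexing) is
deterministic.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReadRecord",
    "ReadPair",
    "Contig",
    "FastqParseError",
    "phred_error_prob",
    "error_probs",
    "read_fastq",
    "read_fastq_pairs",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
]

_ALLOWED = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Raised for a structurally invalid FASTQ record; names the line."""


@dataclass(slots=True)
class ReadRecord:
    """A single sequencing read with its per-base quality string.

    ``mate_index`` is 1 or 2 for a read that is part of a pair, or ``None``
    for an orphan (a read whose mate was removed by filtering).
    """

    id: str
    seq: str
    qual: str
    mate_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class ReadPair:
    """An intact read pair (mate 1, mate 2)."""

    r1: ReadRecord
    r2: ReadRecord


@dataclass(slots=True)
class Contig:
    """An assembled transcript sequence tagged with its source assembly."""

    id: str
    seq: str
    source: object | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def phred_error_prob(qual_char: str, offset: int = 33) -> float:
    """Convert one quality character to its base-call error probability.

    The Phred convention: a character encoding quality score Q corresponds
    to an error probability of 10^(-Q/10).
    """
    q = ord(qual_char) - offset
    if q < 0:
        raise ValueError(
            f"quality character {qual_char!r} below the Phred+{offset} range"
        )
    return 10.0 ** (-q / 10.0)


# lookup table: byte value -> error probability (Phred+33)
_PROB_TABLE = np.array(
    [10.0 ** (-(max(b - 33, 0)) / 10.0) if b >= 33 else math.nan for b in range(256)]
)


def error_probs(qual: str, offset: int = 33) -> np.ndarray:
    """Vector of per-base error probabilities for a quality string."""
    codes = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
    if codes.size and codes.min() < offset:
        bad = chr(codes.min())
        raise ValueError(f"quality character {bad!r} below the Phred+{offset} range")
    if offset == 33:
        return _PROB_TABLE[codes]
    q = codes.astype(np.float64) - offset
    return 10.0 ** (-q / 10.0)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _validate_seq(seq: str, read_id: str, line_no: int) -> str:
    seq = seq.upper()
    if not set(seq) <= _ALLOWED:
        bad = sorted(set(seq) - _ALLOWED)
        raise FastqParseError(
            f"line {line_no}: read {read_id!r} contains characters outside "
            f"A/C/G/T/N: {bad}"
        )
    return seq


def read_fastq(
    path: str | Path, mate_index: int | None = None, offset: int = 33
) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (possibly gzipped) 4-line FASTQ file.

    Malformed records raise :class:`FastqParseError` naming the offending
    line number.
    """
    with _open_text(path) as fh:
        line_no = 0
        while True:
            header = fh.readline()
            if not header:
                return
            line_no += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(
                    f"line {line_no}: expected '@' header, got {header[:30]!r}"
                )
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqParseError(f"line {line_no}: truncated FASTQ record")
            line_no += 3
            if not plus.startswith("+"):
                raise FastqParseError(f"line {line_no - 1}: expected '+' separator")
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            seq = _validate_seq(seq, read_id, line_no - 2)
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"line {line_no}: read {read_id!r} sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )
            if offset != 33 and qual:
                # re-encode to Phred+33 so the rest of the pipeline sees one scale
                qual = "".join(chr(ord(c) - offset + 33) for c in qual)
            yield ReadRecord(read_id, seq, qual, mate_index)


def read_fastq_pairs(
    path1: str | Path, path2: str | Path, offset: int = 33
) -> Iterator[ReadPair]:
    """Pair reads positionally across two FASTQ files (record i with record i).

    Id suffix conventions (``/1``, `` 1:N:``) are deliberately not parsed.
    """
    it1 = read_fastq(path1, mate_index=1, offset=offset)
    it2 = read_fastq(path2, mate_index=2, offset=offset)
    for r1 in it1:
        try:
            r2 = next(it2)
        except StopIteration:
            raise FastqParseError(
                f"{path2}: fewer records than {path1}"
            ) from None
        yield ReadPair(r1, r2)
    try:
        next(it2)
    except StopIteration:
        return
    raise FastqParseError(f"{path2}: more records than {path1}")


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write 4-line FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path, source: object | None = None) -> list[Contig]:
    """Load a FASTA file as a list of Contigs tagged with ``source``."""
    contigs: list[Contig] = []
    with _open_text(path) as fh:
        for rec in _BioSeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not set(seq) <= _ALLOWED:
                bad = sorted(set(seq) - _ALLOWED)
                raise ValueError(
                    f"{path}: contig {rec.id!r} contains characters outside "
                    f"A/C/G/T/N: {bad}"
                )
            contigs.append(Contig(rec.id, seq, source))
    return contigs


def write_fasta(
    contigs: Iterable[Contig], path: str | Path, line_width: int = 60
) -> int:
    """Write contigs as wrapped FASTA; returns the number of records."""
    records = [SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs]
    with _open_text(path, "wt") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        return writer.write_file(records)
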