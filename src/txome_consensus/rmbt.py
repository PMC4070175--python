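"""Reads-mapped-back-to-transcripts (RMBT) validation.

Reads held out of the assembly (typically the unselected complement from
subsampling) are aligned end-to-end against the transcript set; the
fraction of reads that align is a validity metric of the assembly. The
native mapper replaces the external aligner with an auditable model: a hit
requires the FULL read to align without gaps or clipping on either strand,
with at most ``floor(max_mismatch_rate * read_length)`` substitutions.
Among competing hits the minimum-mismatch one wins, ties broken by
transcript id then position. Multi-mapping reads count once; each mate is
counted individually.

A SAM adapter (:func:`rmbt_from_sam`) is provided so the percentage can be
taken from an external end-to-end mapper's output instead.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import Contig, ReadRecord, reverse_complement

__all__ = [
    "MappingParams",
    "Hit",
    "MappingResult",
    "TranscriptIndex",
    "map_read",
    "map_reads",
    "rmbt_percent",
    "rmbt_from_sam",
]

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(slots=True)
class MappingParams:
    """End-to-end mapping parameters.

    seed_length
        Exact-match seed length of the k-mer index (default 22). For short
        reads the effective seed shrinks so that the pigeonhole guarantee
        (one clean seed among mismatch_budget + 1 disjoint segments) holds.
    max_mismatch_rate
        Mismatch budget as a fraction of read length (default 0.04, i.e.
        up to 4 substitutions in a 100 bp read).
    """

    seed_length: int = 22
    max_mismatch_rate: float = 0.04

    def __post_init__(self) -> None:
        if self.seed_length < 10:
            raise ValueError("seed_length must be >= 10")
        if not 0.0 <= self.max_mismatch_rate < 0.5:
            raise ValueError("max_mismatch_rate must be in [0, 0.5)")


@dataclass(slots=True)
class Hit:
    transcript_id: str
    pos: int  # 0-based start on the forward transcript strand
    strand: str  # '+' or '-'
    mismatches: int


class TranscriptIndex:
    """Exact k-mer index over a transcript set (forward strand).

    Minus-strand hits are found by querying the reverse complement of the
    read, so the index itself stores one strand only. Seed tables for the
    k values actually requested are built lazily and cached.
    """

    def __init__(self, transcripts: Sequence[Contig]):
        if not transcripts:
            raise ValueError("TranscriptIndex: empty transcript set")
        self.ids = [t.id for t in transcripts]
        self.seqs = [_encode(t.seq) for t in transcripts]
        self._kmer_tables: dict[int, dict[bytes, list[tuple[int, int]]]] = {}

    def _table(self, k: int) -> dict[bytes, list[tuple[int, int]]]:
        tbl = self._kmer_tables.get(k)
        if tbl is None:
            tbl = defaultdict(list)
            for tidx, arr in enumerate(self.seqs):
                buf = arr.tobytes()
                for pos in range(len(buf) - k + 1):
                    tbl[buf[pos : pos + k]].append((tidx, pos))
            self._kmer_tables[k] = tbl
        return tbl


def _mismatches(tseq: np.ndarray, start: int, read_arr: np.ndarray) -> int:
    return int((tseq[start : start + read_arr.size] != read_arr).sum())


def _candidates_seeded(
    index: TranscriptIndex, read_arr: np.ndarray, k: int, n_segments: int
) -> set[tuple[int, int]]:
    table = index._table(k)
    buf = read_arr.tobytes()
    L = read_arr.size
    cands: set[tuple[int, int]] = set()
    for seg in range(n_segments):
        off = seg * k
        for tidx, pos in table.get(buf[off : off + k], ()):
            start = pos - off
            if 0 <= start <= index.seqs[tidx].size - L:
                cands.add((tidx, start))
    return cands


def map_read(
    read: ReadRecord | str,
    index: TranscriptIndex,
    params: MappingParams | None = None,
) -> Hit | None:
    """Best end-to-end hit of one read against the index, or None.

    Pigeonhole seeding: the read is split into (mismatch budget + 1)
    disjoint segments; any placement within budget must match at least one
    segment exactly, so the seeded candidate set is exhaustive. Reads too
    short to carry enough segments fall back to a full scan.
    """
    params = params or MappingParams()
    seq = read if isinstance(read, str) else read.seq
    L = len(seq)
    if L == 0:
        return None
    budget = int(params.max_mismatch_rate * L)
    n_segments = budget + 1
    k = min(params.seed_length, L // n_segments)

    best: tuple[int, str, int, str] | None = None  # (mm, tid, pos, strand)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        arr = _encode(s)
        if k >= 8:
            cands = _candidates_seeded(index, arr, k, n_segments)
        else:  # read too short for guaranteed seeding: exhaustive scan
            cands = {
                (tidx, start)
                for tidx, tseq in enumerate(index.seqs)
                for start in range(tseq.size - L + 1)
            }
        for tidx, start in cands:
            mm = _mismatches(index.seqs[tidx], start, arr)
            if mm <= budget:
                key = (mm, index.ids[tidx], start, strand)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    mm, tid, pos, strand = best
    return Hit(tid, pos, strand, mm)


@dataclass(slots=True)
class MappingResult:
    n_reads: int
    n_mapped: int
    hits: dict[str, Hit | None] = field(default_factory=dict)


def map_reads(
    reads: Iterable[ReadRecord],
    index: TranscriptIndex,
    params: MappingParams | None = None,
    keep_hits: bool = True,
) -> MappingResult:
    """Map each read individually; mates are not required to be concordant."""
    params = params or MappingParams()
    n = mapped = 0
    hits: dict[str, Hit | None] = {}
    for read in reads:
        h = map_read(read, index, params)
        n += 1
        if h is not None:
            mapped += 1
        if keep_hits:
            key = read.id if read.mate_index is None else f"{read.id}/{read.mate_index}"
            hits[key] = h
    return MappingResult(n, mapped, hits)


def rmbt_percent(result: MappingResult) -> float:
    """Percentage of reads with an end-to-end hit."""
    if result.n_reads == 0:
        raise ValueError("rmbt_percent: no reads")
    return 100.0 * result.n_mapped / result.n_reads


def rmbt_from_sam(path: str | Path) -> float:
    """RMBT percentage from an external mapper's SAM output.

    A read counts as mapped when its record does not carry the unmapped
    flag (0x4); secondary/supplementary records are ignored so each read
    counts once.
    """
    import pysam

    n = mapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            n += 1
            if not rec.is_unmapped:
                mapped += 1
    if n == 0:
        raise ValueError(f"{path}: no primary records")
    return 100.0 * mapped / n
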