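"""Read quality control: cumulative-error trimming, duplicate removal,
length filtering, and seeded subsampling.

The trimmer implements the modified-Mott style algorithm used by common
commercial QC tools: each quality score is converted to an error
probability e, the running total of (limit - e) is accumulated and clamped
at zero, and the retained window runs from the first positive value of the
running total to its highest value. Reads whose running total never becomes
positive are discarded outright.

Stage order is fixed as trim -> duplicate removal -> length-keep filter,
and per-stage read counts are collected in a :class:`QCReport` whose table
mirrors the pairs / orphans / sum accounting of a standard QC summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import ReadPair, ReadRecord, error_probs

__all__ = [
    "TrimParams",
    "QCReport",
    "QCResult",
    "SubsampleResult",
    "trim_interval",
    "trim_read",
    "remove_duplicates",
    "length_keep_filter",
    "run_qc",
    "subsample_pairs",
]


@dataclass(slots=True)
class TrimParams:
    """Parameters of the quality-trimming stage.

    limit
        Error-probability threshold of the cumulative trimmer (default 0.05,
        i.e. bases worse than Q13 erode the running total).
    max_ambiguous
        Maximum number of 'N' bases tolerated in the retained window.
    min_len_post_trim
        Reads shorter than this after trimming are discarded (default 20).
    min_len_keep
        Strict lower bound applied after duplicate removal: only reads
        longer than this are kept (default 50).
    """

    limit: float = 0.05
    max_ambiguous: int = 2
    min_len_post_trim: int = 20
    min_len_keep: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.limit < 1.0:
            raise ValueError("limit must be in (0, 1)")
        if self.max_ambiguous < 0:
            raise ValueError("max_ambiguous must be >= 0")
        if self.min_len_post_trim < 1 or self.min_len_keep < 1:
            raise ValueError("minimum lengths must be >= 1")


def trim_interval(
    error_probs_: Sequence[float] | np.ndarray, limit: float = 0.05
) -> tuple[int, int] | None:
    """Retained window of a read under the cumulative-error trimmer.

    Returns a 1-based inclusive interval ``(start, end)``, or ``None`` when
    the whole read is discarded. The recurrence

        s(0) = 0,  s(i) = max(0, s(i-1) + (limit - e(i)))

    is evaluated literally, in sequence. The window ends at the last
    position attaining the maximum of s (a tie is resolved toward the
    longer read) and starts at the beginning of the final positive run
    containing that end.
    """
    e = (
        error_probs_.tolist()
        if isinstance(error_probs_, np.ndarray)
        else list(error_probs_)
    )
    if not e:
        raise ValueError("trim_interval: empty error-probability vector")
    s = 0.0
    best = 0.0
    end = -1
    run_start = -1
    current_run_start = -1
    for i, ei in enumerate(e):
        s += limit - ei
        if s > 0.0:
            if current_run_start < 0:
                current_run_start = i
            if s >= best:  # >=: the LAST maximum wins
                best = s
                end = i
                run_start = current_run_start
        else:
            s = 0.0
            current_run_start = -1
    if end < 0:
        return None
    return (run_start + 1, end + 1)


def trim_read(read: ReadRecord, params: TrimParams) -> ReadRecord | None:
    """Trim one read; returns the trimmed record or ``None`` if discarded.

    A read is discarded when the trimmer retains nothing, when the retained
    window is shorter than ``min_len_post_trim``, or when it contains more
    than ``max_ambiguous`` 'N' bases.
    """
    if len(read) == 0:
        return None
    iv = trim_interval(error_probs(read.qual), params.limit)
    if iv is None:
        return None
    start, end = iv
    seq = read.seq[start - 1 : end]
    if len(seq) < params.min_len_post_trim:
        return None
    if seq.count("N") > params.max_ambiguous:
        return None
    return ReadRecord(read.id, seq, read.qual[start - 1 : end], read.mate_index)


def _trim_stage(
    pairs: Sequence[ReadPair], orphans: Sequence[ReadRecord], params: TrimParams
) -> tuple[list[ReadPair], list[ReadRecord]]:
    out_pairs: list[ReadPair] = []
    out_orphans: list[ReadRecord] = []
    for p in pairs:
        t1 = trim_read(p.r1, params)
        t2 = trim_read(p.r2, params)
        if t1 is not None and t2 is not None:
            out_pairs.append(ReadPair(t1, t2))
        elif t1 is not None:
            out_orphans.append(t1)
        elif t2 is not None:
            out_orphans.append(t2)
    for o in orphans:
        t = trim_read(o, params)
        if t is not None:
            out_orphans.append(t)
    return out_pairs, out_orphans


def remove_duplicates(
    pairs: Sequence[ReadPair], orphans: Sequence[ReadRecord]
) -> tuple[list[ReadPair], list[ReadRecord]]:
    """Keep the first occurrence of each duplicate class.

    Pairs are duplicates when the ordered tuple (r1.seq, r2.seq) matches
    exactly; orphans when the sequence matches exactly. No
    reverse-complement collapsing. Idempotent.
    """
    seen_pairs: set[tuple[str, str]] = set()
    out_pairs: list[ReadPair] = []
    for p in pairs:
        key = (p.r1.seq, p.r2.seq)
        if key not in seen_pairs:
            seen_pairs.add(key)
            out_pairs.append(p)
    seen_orphans: set[str] = set()
    out_orphans: list[ReadRecord] = []
    for o in orphans:
        if o.seq not in seen_orphans:
            seen_orphans.add(o.seq)
            out_orphans.append(o)
    return out_pairs, out_orphans


def length_keep_filter(
    pairs: Sequence[ReadPair],
    orphans: Sequence[ReadRecord],
    min_len_keep: int = 50,
) -> tuple[list[ReadPair], list[ReadRecord]]:
    """Keep only reads strictly longer than ``min_len_keep``.

    A pair with exactly one failing mate is broken: the surviving mate
    becomes an orphan.
    """
    out_pairs: list[ReadPair] = []
    out_orphans: list[ReadRecord] = []
    for p in pairs:
        ok1 = len(p.r1) > min_len_keep
        ok2 = len(p.r2) > min_len_keep
        if ok1 and ok2:
            out_pairs.append(p)
        elif ok1:
            out_orphans.append(p.r1)
        elif ok2:
            out_orphans.append(p.r2)
    out_orphans.extend(o for o in orphans if len(o) > min_len_keep)
    return out_pairs, out_orphans


_STAGES = ("raw", "trimmed", "after_dup_all", "after_dup_gt_keep")


@dataclass(slots=True)
class QCReport:
    """Per-stage read accounting (reads in intact pairs, orphans, sum).

    ``counts[stage]`` maps to ``{"paired_reads": int, "orphans": int,
    "sum": int}`` for each of the four stages raw, trimmed, after_dup_all,
    after_dup_gt_keep.
    """

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def record(self, stage: str, pairs: Sequence[ReadPair], orphans: Sequence) -> None:
        paired_reads = 2 * len(pairs)
        self.counts[stage] = {
            "paired_reads": paired_reads,
            "orphans": len(orphans),
            "sum": paired_reads + len(orphans),
        }

    def to_frame(self) -> pd.DataFrame:
        stages = [s for s in _STAGES if s in self.counts]
        data = {
            "stage": stages,
            "paired_reads": [self.counts[s]["paired_reads"] for s in stages],
            "orphans": [self.counts[s]["orphans"] for s in stages],
            "sum": [self.counts[s]["sum"] for s in stages],
        }
        return pd.DataFrame(data)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(slots=True)
class QCResult:
    pairs: list[ReadPair]
    orphans: list[ReadRecord]
    report: QCReport


def run_qc(
    pairs: Sequence[ReadPair],
    orphans: Sequence[ReadRecord] = (),
    params: TrimParams | None = None,
) -> QCResult:
    """Run the full QC chain: trim -> duplicate removal -> length-keep."""
    params = params or TrimParams()
    report = QCReport()
    report.record("raw", pairs, orphans)

    pairs1, orphans1 = _trim_stage(pairs, orphans, params)
    report.record("trimmed", pairs1, orphans1)

    pairs2, orphans2 = remove_duplicates(pairs1, orphans1)
    report.record("after_dup_all", pairs2, orphans2)

    pairs3, orphans3 = length_keep_filter(pairs2, orphans2, params.min_len_keep)
    report.record("after_dup_gt_keep", pairs3, orphans3)

    return QCResult(pairs3, orphans3, report)


@dataclass(slots=True)
class SubsampleResult:
    """Seeded random split of read pairs into selected / unselected."""

    selected: list[ReadPair]
    unselected: list[ReadPair]
    seed: int
    algorithm: str = "numpy.random.Generator(PCG64).permutation"


def subsample_pairs(pairs: Sequence[ReadPair], n: int, seed: int) -> SubsampleResult:
    """Uniform random n-subset of pairs without replacement (seeded).

    The complement is returned as ``unselected``; both sides preserve the
    original input order. Orphan reads are never subsampled.
    """
    if not 0 <= n <= len(pairs):
        raise ValueError(f"subsample size {n} outside [0, {len(pairs)}]")
    rng = np.random.default_rng(seed)
    chosen = np.zeros(len(pairs), dtype=bool)
    chosen[rng.permutation(len(pairs))[:n]] = True
    selected = [p for p, c in zip(pairs, chosen) if c]
    unselected = [p for p, c in zip(pairs, chosen) if not c]
    return SubsampleResult(selected, unselected, seed)
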