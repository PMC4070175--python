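"""Assembly evaluation metrics and k-mer selection.

Seven statistics are computed per assembly: number of transcripts, total
bases, mean transcript length, N50, the reads-mapped-back-to-transcripts
percentage (RMBT, computed by :mod:`txome_consensus.rmbt`), the number of
long transcripts (> 1 kb), and the core-gene completeness percentages
(:mod:`txome_consensus.completeness`). Unless stated otherwise, statistics
are computed over non-redundant sequences strictly longer than 200 bp.

N50 follows the community convention: the largest contig length L such
that contigs of length >= L together cover at least half of the total
assembly length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import Contig

__all__ = [
    "MetricsRow",
    "KSelectionParams",
    "n50",
    "assembly_stats",
    "select_k",
    "k_sweep_table",
    "valid_k_range",
    "metrics_table",
]


@dataclass(slots=True)
class MetricsRow:
    """One row of the per-assembly evaluation table."""

    assembly_label: str
    n_transcripts: int
    total_bp: int
    mean_len: float
    n50: int
    n_long: int
    rmbt_pct: float | None = None
    completeness: tuple[float, float] | None = None  # (complete %, partial %)

    def as_dict(self) -> dict:
        comp, part = self.completeness if self.completeness else (None, None)
        return {
            "assembly": self.assembly_label,
            "n_transcripts": self.n_transcripts,
            "total_bp": self.total_bp,
            "mean_len": round(self.mean_len, 2),
            "n50": self.n50,
            "rmbt_pct": None if self.rmbt_pct is None else round(self.rmbt_pct, 2),
            "n_long": self.n_long,
            "complete_pct": None if comp is None else round(comp, 2),
            "partial_pct": None if part is None else round(part, 2),
        }


@dataclass(slots=True)
class KSelectionParams:
    """Parameters for choosing a single-k assembly per tool.

    ``length_retention_fraction`` operationalizes "maximize N50 while
    keeping the total assembly length as long as possible" as a Pareto
    filter: only candidates whose total length is at least this fraction of
    the best candidate's total are eligible for the N50 comparison.
    """

    length_retention_fraction: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 < self.length_retention_fraction <= 1.0:
            raise ValueError("length_retention_fraction must be in (0, 1]")


def n50(lengths: Iterable[int]) -> int:
    """N50 of a multiset of contig lengths.

    The largest length L present in the multiset such that contigs of
    length >= L sum to at least half the total.
    """
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50: empty length set")
    if (arr <= 0).any():
        raise ValueError("n50: lengths must be positive")
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return int(arr[idx])


def assembly_stats(
    assembly: Sequence[Contig],
    label: str = "",
    min_len: int = 200,
    long_threshold: int = 1000,
) -> MetricsRow:
    """Length statistics of an assembly over contigs strictly > ``min_len``.

    RMBT and completeness are left unset; callers fill them in from the
    dedicated modules.
    """
    lengths = [len(c) for c in assembly if len(c) > min_len]
    if not lengths:
        raise ValueError(f"assembly {label!r}: no contigs longer than {min_len} bp")
    total = sum(lengths)
    return MetricsRow(
        assembly_label=label,
        n_transcripts=len(lengths),
        total_bp=total,
        mean_len=total / len(lengths),
        n50=n50(lengths),
        n_long=sum(1 for L in lengths if L > long_threshold),
    )


def select_k(
    candidates: Sequence[tuple[int, MetricsRow]],
    params: KSelectionParams | None = None,
) -> int:
    """Pick the k maximizing N50 among sufficiently long assemblies.

    Eligible candidates have total_bp >= f * (max total_bp); among those the
    one with the highest N50 wins, ties going to the smaller k.
    """
    if not candidates:
        raise ValueError("select_k: no candidates")
    params = params or KSelectionParams()
    t_star = max(row.total_bp for _, row in candidates)
    eligible = [
        (k, row)
        for k, row in candidates
        if row.total_bp >= params.length_retention_fraction * t_star
    ]
    return min(eligible, key=lambda kr: (-kr[1].n50, kr[0]))[0]


def k_sweep_table(per_k_stats: Sequence[tuple[int, MetricsRow]]) -> pd.DataFrame:
    """(k, N50, total bp) table sorted by k, for k-sweep plots."""
    if not per_k_stats:
        raise ValueError("k_sweep_table: no entries")
    ks = [k for k, _ in per_k_stats]
    if len(set(ks)) != len(ks):
        raise ValueError("k_sweep_table: duplicate k values")
    rows = sorted(per_k_stats, key=lambda kr: kr[0])
    return pd.DataFrame(
        {
            "k": [k for k, _ in rows],
            "n50": [r.n50 for _, r in rows],
            "total_bp": [r.total_bp for _, r in rows],
        }
    )


def valid_k_range(mean_read_length: float) -> list[int]:
    """Suggested odd k-mer values: 21 up to (mean read length - 10)."""
    upper = int(mean_read_length - 10)
    return [k for k in range(21, upper + 1) if k % 2 == 1]


def metrics_table(rows: Iterable[MetricsRow]) -> pd.DataFrame:
    """Assemble MetricsRows into the seven-column evaluation table."""
    return pd.DataFrame([r.as_dict() for r in rows])
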