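"""Within-assembly redundancy removal (cd-hit-est style).

Shorter transcripts sharing more than ``identity_threshold`` identity with
a longer retained transcript are removed, then transcripts not strictly
longer than ``min_len_keep`` are dropped. Identity follows the shorter-
sequence convention: aligned matches divided by the length of the shorter
sequence, so exact containment scores 1.0. Both strands are compared and
the higher identity wins, since de novo transcript orientation is
arbitrary.

The greedy longest-first sweep is exact at the scales this package targets:
a q-gram (shared word count) lower bound is used only to skip alignments
that provably cannot reach the threshold, so the result is identical to
exhaustive all-pairs comparison.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import edlib

from .seqio import Contig, reverse_complement

__all__ = [
    "ClusterParams",
    "pairwise_identity",
    "cluster_transcripts",
    "ClusterResult",
]


@dataclass(slots=True)
class ClusterParams:
    """Parameters of the redundancy-removal step.

    identity_threshold
        Transcripts sharing strictly more than this identity with a longer
        retained transcript are removed (default 0.99).
    min_len_keep
        Strict length cutoff applied after clustering (default 200 bp).
    word_size
        Word length of the q-gram prefilter (speed only; never changes the
        result).
    """

    identity_threshold: float = 0.99
    min_len_keep: int = 200
    word_size: int = 10

    def __post_init__(self) -> None:
        if not 0.5 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0.5, 1]")
        if self.min_len_keep < 1:
            raise ValueError("min_len_keep must be >= 1")


def _identity_one_strand(shorter: str, longer: str) -> float:
    # infix (HW) alignment: the shorter sequence may start/end anywhere in
    # the longer one; edit distance bounds the number of non-matching
    # columns, so (Ls - d) / Ls is the containment-style identity.
    d = edlib.align(shorter, longer, mode="HW", task="distance")["editDistance"]
    return max(0.0, (len(shorter) - d) / len(shorter))


def pairwise_identity(a: str, b: str, both_strands: bool = True) -> float:
    """Identity between two sequences over the length of the shorter one.

    Computed from the best infix alignment of the shorter sequence within
    the longer (either strand when ``both_strands``); symmetric in its
    arguments. An exact substring scores 1.0.
    """
    if not a or not b:
        raise ValueError("pairwise_identity: empty sequence")
    if len(a) == len(b):
        # infix alignment is direction-dependent at equal lengths (free end
        # gaps apply to the target only); take both directions for symmetry
        orders = [(a, b), (b, a)]
    else:
        orders = [(a, b) if len(a) < len(b) else (b, a)]
    ident = 0.0
    for shorter, longer in orders:
        ident = max(ident, _identity_one_strand(shorter, longer))
        if both_strands and ident < 1.0:
            ident = max(
                ident, _identity_one_strand(reverse_complement(shorter), longer)
            )
        if ident == 1.0:
            break
    return ident


def _words(seq: str, w: int) -> list[str]:
    return [seq[i : i + w] for i in range(len(seq) - w + 1)]


def _qgram_bound(ls: int, w: int, threshold: float) -> int:
    """Minimum shared word count implied by identity > threshold over a
    shorter length ``ls`` (q-gram lemma); <= 0 disables the prefilter."""
    # identity > t  <=>  edit distance d < ls * (1 - t)
    d_max = math.ceil(ls * (1.0 - threshold) - 1e-9) - 1
    return (ls - w + 1) - d_max * w


@dataclass(slots=True)
class ClusterResult:
    retained: list[Contig]
    members: dict[str, list[str]]  # representative id -> removed member ids


def cluster_transcripts(
    assembly: Sequence[Contig], params: ClusterParams | None = None
) -> ClusterResult:
    """Greedy longest-first redundancy clustering of one assembly.

    Contigs are visited longest first (ties by input order); a contig whose
    identity to any retained representative exceeds the threshold is
    removed and recorded under that representative. Finally, retained
    contigs not strictly longer than ``min_len_keep`` are dropped.
    Deterministic and idempotent.
    """
    params = params or ClusterParams()
    w = params.word_size
    order = sorted(range(len(assembly)), key=lambda i: (-len(assembly[i]), i))

    word_index: dict[str, list[int]] = defaultdict(list)  # word -> retained idx
    retained_idx: list[int] = []
    members: dict[str, list[str]] = {}

    for i in order:
        seq = assembly[i].seq
        removed = False
        if retained_idx:
            bound = _qgram_bound(len(seq), w, params.identity_threshold)
            if bound <= 0 or len(seq) < w:
                check = sorted(retained_idx)
            else:
                candidates: dict[int, int] = defaultdict(int)
                for strand_seq in (seq, reverse_complement(seq)):
                    strand_counts: dict[int, int] = defaultdict(int)
                    for word in _words(strand_seq, w):
                        for ridx in word_index.get(word, ()):
                            strand_counts[ridx] += 1
                    for ridx, cnt in strand_counts.items():
                        candidates[ridx] = max(candidates[ridx], cnt)
                # q-gram lemma: fewer shared words than the bound proves the
                # identity cannot exceed the threshold
                check = sorted(r for r, c in candidates.items() if c >= bound)
            for ridx in check:
                rep = assembly[ridx]
                if pairwise_identity(seq, rep.seq) > params.identity_threshold:
                    members.setdefault(rep.id, []).append(assembly[i].id)
                    removed = True
                    break
        if not removed:
            retained_idx.append(i)
            members.setdefault(assembly[i].id, [])
            for word in set(_words(seq, w)):
                word_index[word].append(i)

    keep = [
        assembly[i]
        for i in sorted(retained_idx)
        if len(assembly[i]) > params.min_len_keep
    ]
    kept_ids = {c.id for c in keep}
    members = {rid: mids for rid, mids in members.items() if rid in kept_ids}
    return ClusterResult(keep, members)
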