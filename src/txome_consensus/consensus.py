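"""Multi-assembly consensus merging with provenance, and the robust filter.

Assemblies produced by different tools (and different k-mer values) are
pooled and transitively overlapping contigs are merged into consensus
sequences, in the manner of an overlap-layout-consensus assembler run on
contigs. Every merged contig records its constituents — which input contig
from which (tool, k) assembly was placed where — so that "robust" contigs,
those whose constituents come from at least ``min_tools`` distinct tools,
can be selected afterwards. Contig ids are namespaced with their source
label when pooled, so provenance survives any merge backend.

Overlap detection considers both orientations of the second sequence and
accepts the best ungapped suffix-prefix or containment overlap of length
>= ``min_overlap`` and identity >= ``min_overlap_identity`` (defaults 40 bp
and 90%, mirroring the documented defaults of the classical overlap
assembler). Consensus calls the majority base per column, ties resolved by
the longest constituent.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import Contig, reverse_complement

__all__ = [
    "SourceLabel",
    "MergeParams",
    "Overlap",
    "Constituent",
    "MergedContig",
    "find_overlap",
    "merge_assemblies",
    "robust_filter",
]

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENC[_b] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


@dataclass(frozen=True, slots=True)
class SourceLabel:
    """Identity of an input assembly: tool name plus k-mer tag ("MK",
    "merged", an integer, ...)."""

    tool: str
    k: object = None

    def __post_init__(self) -> None:
        if not self.tool:
            raise ValueError("SourceLabel: tool name must be non-empty")

    def __str__(self) -> str:
        return self.tool if self.k is None else f"{self.tool}_{self.k}"


@dataclass(slots=True)
class MergeParams:
    min_overlap: int = 40
    min_overlap_identity: float = 0.90
    min_tools: int = 3

    def __post_init__(self) -> None:
        if self.min_overlap < 10:
            raise ValueError("min_overlap must be >= 10")
        if not 0.5 <= self.min_overlap_identity <= 1.0:
            raise ValueError("min_overlap_identity must be in [0.5, 1]")
        if self.min_tools < 1:
            raise ValueError("min_tools must be >= 1")


@dataclass(slots=True)
class Overlap:
    """An ungapped overlap of (oriented) b against a.

    ``offset`` is the start of the oriented b on a's coordinate axis (may
    be negative: b hangs off a's left end). ``orientation`` is +1 when b is
    used forward, -1 when reverse-complemented. ``containment`` marks one
    sequence lying entirely within the other.
    """

    length: int
    identity: float
    orientation: int
    offset: int
    matches: int
    containment: bool


_SEED_K = 16
_EXHAUSTIVE_LIMIT = 2_000_000


def _diagonal_score(a: np.ndarray, b: np.ndarray, d: int) -> tuple[int, int]:
    """(overlap length, matches) of the ungapped placement of b at offset d."""
    s = max(0, d)
    e = min(a.size, d + b.size)
    if e <= s:
        return 0, 0
    seg_a = a[s:e]
    seg_b = b[s - d : e - d]
    return e - s, int((seg_a == seg_b).sum())


def _candidate_diagonals(a: np.ndarray, b: np.ndarray, min_overlap: int) -> list[int]:
    """Diagonals sharing at least one exact 16-mer (seeded path)."""
    k = min(_SEED_K, min(a.size, b.size))
    index: dict[bytes, list[int]] = defaultdict(list)
    abuf = a.tobytes()
    for pos in range(a.size - k + 1):
        index[abuf[pos : pos + k]].append(pos)
    bbuf = b.tobytes()
    diags: set[int] = set()
    for j in range(b.size - k + 1):
        for pos in index.get(bbuf[j : j + k], ()):
            diags.add(pos - j)
    return sorted(diags)


def find_overlap(
    a: str | Contig,
    b: str | Contig,
    params: MergeParams | None = None,
    exhaustive: bool | None = None,
) -> Overlap | None:
    """Best ungapped overlap between a and b (either orientation of b).

    All diagonals are evaluated exhaustively (vectorized) when the product
    of lengths is small; larger inputs use diagonals seeded by shared exact
    16-mers, which finds the same overlaps whenever the true overlap
    contains an exact 16-mer run (always the case at the low divergence
    levels consensus merging targets). Returns ``None`` when no placement
    reaches ``min_overlap`` length and ``min_overlap_identity``.
    """
    params = params or MergeParams()
    a_seq = a.seq if isinstance(a, Contig) else a
    b_seq = b.seq if isinstance(b, Contig) else b
    if min(len(a_seq), len(b_seq)) < params.min_overlap:
        return None
    if exhaustive is None:
        exhaustive = len(a_seq) * len(b_seq) <= _EXHAUSTIVE_LIMIT
    a_arr = _encode(a_seq)
    best: Overlap | None = None
    for orient, b_oriented in ((1, b_seq), (-1, reverse_complement(b_seq))):
        b_arr = _encode(b_oriented)
        if exhaustive:
            diags: Iterable[int] = range(
                -(b_arr.size - params.min_overlap), a_arr.size - params.min_overlap + 1
            )
        else:
            diags = _candidate_diagonals(a_arr, b_arr, params.min_overlap)
        for d in diags:
            length, matches = _diagonal_score(a_arr, b_arr, d)
            if length < params.min_overlap:
                continue
            identity = matches / length
            if identity < params.min_overlap_identity:
                continue
            cand = Overlap(
                length=length,
                identity=identity,
                orientation=orient,
                offset=d,
                matches=matches,
                containment=(d >= 0 and d + b_arr.size <= a_arr.size)
                or (d <= 0 and d + b_arr.size >= a_arr.size),
            )
            key = (cand.matches, cand.length, -abs(cand.offset), cand.orientation)
            if best is None or key > (
                best.matches,
                best.length,
                -abs(best.offset),
                best.orientation,
            ):
                best = cand
    return best


@dataclass(slots=True)
class Constituent:
    contig_id: str
    source: SourceLabel
    offset: int  # placement on the merged contig's axis
    strand: int  # +1 / -1
    length: int


@dataclass(slots=True)
class MergedContig:
    id: str
    seq: str
    constituents: list[Constituent]

    @property
    def n_tools(self) -> int:
        return len({c.source.tool for c in self.constituents})

    @property
    def source_labels(self) -> set[SourceLabel]:
        return {c.source for c in self.constituents}


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def _candidate_pairs(arrs: list[np.ndarray]) -> list[tuple[int, int]]:
    """Pairs of pooled contigs sharing an exact 16-mer on either strand."""
    k = _SEED_K
    word_owner: dict[bytes, list[int]] = defaultdict(list)
    for i, arr in enumerate(arrs):
        buf = arr.tobytes()
        seen: set[bytes] = set()
        for pos in range(arr.size - k + 1):
            word = buf[pos : pos + k]
            if word not in seen:
                seen.add(word)
                word_owner[word].append(i)
    pairs: set[tuple[int, int]] = set()
    for owners in word_owner.values():
        if 1 < len(owners) <= 50:  # highly repeated words are uninformative
            for x in range(len(owners)):
                for y in range(x + 1, len(owners)):
                    pairs.add((owners[x], owners[y]))
    # reverse-complement sharing: index rc words of each contig against owners
    for i, arr in enumerate(arrs):
        rc = _encode(reverse_complement(_decode(arr)))
        buf = rc.tobytes()
        seen = set()
        for pos in range(rc.size - k + 1):
            word = buf[pos : pos + k]
            if word in seen:
                continue
            seen.add(word)
            for j in word_owner.get(word, ()):
                if j != i:
                    pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


def merge_assemblies(
    assemblies: Sequence[tuple[SourceLabel, Sequence[Contig]]],
    params: MergeParams | None = None,
) -> list[MergedContig]:
    """Merge labeled assemblies into consensus contigs with provenance.

    Contigs are pooled under namespaced ids (``tool_k|original-id``),
    pairwise overlaps passing the thresholds connect them into components,
    each component is laid out by composing overlap placements from its
    longest contig outward, and the consensus takes the majority base per
    column (ties -> the longest constituent's base). Unmerged contigs
    become singlets; every input contig appears in exactly one merged
    contig's constituent list.
    """
    params = params or MergeParams()
    if not assemblies:
        raise ValueError("merge_assemblies: no input assemblies")

    pool_ids: list[str] = []
    pool_labels: list[SourceLabel] = []
    arrs: list[np.ndarray] = []
    for label, contigs in assemblies:
        for c in contigs:
            pool_ids.append(f"{label}|{c.id}")
            pool_labels.append(label)
            arrs.append(_encode(c.seq))
    n = len(arrs)

    # overlap graph over seed-sharing candidate pairs
    uf = _UnionFind(n)
    adjacency: dict[int, list[tuple[int, int, int]]] = defaultdict(list)
    for i, j in _candidate_pairs(arrs):
        a_len, b_len = arrs[i].size, arrs[j].size
        if min(a_len, b_len) < params.min_overlap:
            continue
        ov = find_overlap(_decode(arrs[i]), _decode(arrs[j]), params, exhaustive=False)
        if ov is None:
            continue
        # forward edge i -> j and the algebraically inverted edge j -> i
        adjacency[i].append((j, ov.orientation, ov.offset))
        if ov.orientation == 1:
            adjacency[j].append((i, 1, -ov.offset))
        else:
            adjacency[j].append((i, -1, ov.offset + b_len - a_len))
        uf.union(i, j)

    components: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        components[uf.find(i)].append(i)

    merged: list[MergedContig] = []
    for root in sorted(components):
        members = components[root]
        if len(members) == 1:
            i = members[0]
            merged.append(
                MergedContig(
                    id=f"merged_{len(merged) + 1}",
                    seq=_decode(arrs[i]),
                    constituents=[
                        Constituent(pool_ids[i], pool_labels[i], 0, 1, arrs[i].size)
                    ],
                )
            )
            continue
        placements = _layout(members, arrs, adjacency)
        seq, constituents = _consensus(members, arrs, placements, pool_ids, pool_labels)
        merged.append(
            MergedContig(id=f"merged_{len(merged) + 1}", seq=seq, constituents=constituents)
        )
    return merged


def _layout(
    members: list[int],
    arrs: list[np.ndarray],
    adjacency: dict[int, list[tuple[int, int, int]]],
) -> dict[int, tuple[int, int]]:
    """Compose overlap placements into (strand, offset) per member contig.

    Anchored at the longest member (forward, offset 0); breadth-first over
    overlap edges; on conflicting placements the first one wins.
    """
    anchor = max(members, key=lambda i: (arrs[i].size, -i))
    placements: dict[int, tuple[int, int]] = {anchor: (1, 0)}
    queue = [anchor]
    while queue:
        i = queue.pop(0)
        si, oi = placements[i]
        li = arrs[i].size
        for j, orient, d in adjacency[i]:
            if j in placements:
                continue
            sj = si * orient
            lj = arrs[j].size
            oj = oi + d if si == 1 else oi + li - (d + lj)
            placements[j] = (sj, oj)
            queue.append(j)
    # members unreachable through edges (cannot happen for union-find
    # components, but guard anyway): place at the end, forward
    tail = max(o + arrs[i].size for i, (s, o) in placements.items())
    for i in members:
        if i not in placements:
            placements[i] = (1, tail)
            tail += arrs[i].size
    return placements


def _consensus(
    members: list[int],
    arrs: list[np.ndarray],
    placements: dict[int, tuple[int, int]],
    pool_ids: list[str],
    pool_labels: list[SourceLabel],
) -> tuple[str, list[Constituent]]:
    min_off = min(placements[i][1] for i in members)
    span = max(placements[i][1] + arrs[i].size for i in members) - min_off
    counts = np.zeros((span, 5), dtype=np.int32)
    oriented: dict[int, np.ndarray] = {}
    for i in members:
        strand, off = placements[i]
        arr = arrs[i] if strand == 1 else _encode(reverse_complement(_decode(arrs[i])))
        oriented[i] = arr
        cols = np.arange(off - min_off, off - min_off + arr.size)
        np.add.at(counts, (cols, arr), 1)

    maxc = counts.max(axis=1)
    called = np.full(span, -1, dtype=np.int8)
    for i in sorted(members, key=lambda m: (-arrs[m].size, m)):
        _, off = placements[i]
        arr = oriented[i]
        cols = np.arange(off - min_off, off - min_off + arr.size)
        take = (called[cols] < 0) & (counts[cols, arr] == maxc[cols])
        called[cols[take]] = arr[take]
    called[called < 0] = 4  # uncovered columns (disjoint placements) -> N

    constituents = [
        Constituent(
            pool_ids[i],
            pool_labels[i],
            placements[i][1] - min_off,
            placements[i][0],
            arrs[i].size,
        )
        for i in sorted(members)
    ]
    return _decode(called.astype(np.uint8)), constituents


def robust_filter(
    merged: Sequence[MergedContig],
    min_tools: int = 3,
    require_labels: Iterable[SourceLabel] | None = None,
) -> list[MergedContig]:
    """Retain merged contigs assembled by at least ``min_tools`` tools.

    In strict mode (``require_labels``), a contig must instead contain
    constituents from every one of the given input assembly labels.
    """
    if require_labels is not None:
        required = set(require_labels)
        return [m for m in merged if required <= m.source_labels]
    return [m for m in merged if m.n_tools >= min_tools]
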