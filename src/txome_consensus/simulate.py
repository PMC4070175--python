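"""Synthetic ground truth for exercising the whole pipeline.

The generator emulates the study conditions of a bulk RNA-seq assembly
experiment at desk scale: a transcriptome with log-normal transcript
lengths (truncated to 200-10,000 bp) and log-normal expression weights,
paired-end 100 bp reads with an insert size of ~305 +/- 30 bp and
substitution errors, and per-tool "assemblies" of the true transcripts
corrupted by dropout, fragmentation into overlapping pieces, per-base
substitutions, and tool-private random noise contigs. Every simulation
emits a ground-truth map (contig -> source transcript or noise) so that
recall and precision of downstream steps can be measured.

Quality strings are constant high quality (Q40) except at simulated error
positions, which are assigned low quality (Q5), giving the quality trimmer
a real signal to act on. All operations are fully deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .consensus import SourceLabel
from .seqio import Contig, ReadPair, ReadRecord, reverse_complement

__all__ = [
    "SimConfig",
    "ToolProfile",
    "simulate_transcriptome",
    "simulate_reads",
    "simulate_tool_assemblies",
    "simulate_core_genes",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

QUAL_HIGH = "I"  # Q40, error probability 1e-4
QUAL_ERROR = "&"  # Q5, error probability ~0.32


@dataclass(slots=True)
class SimConfig:
    """Study conditions of the synthetic dataset.

    Transcript lengths are log-normal (median ~1 kb) truncated to
    [200, 10,000] bp; expression weights are log-normal. Reads are 100 bp
    paired-end with insert ~ Normal(305, 30) truncated to the feasible
    range, matching a standard short-insert Illumina library.
    """

    n_transcripts: int = 500
    length_log_mean: float = 6.9  # exp(6.9) ~ 992 bp
    length_log_sd: float = 0.55
    min_transcript_len: int = 200
    max_transcript_len: int = 10_000
    expression_log_sd: float = 1.0
    read_len: int = 100
    insert_mean: float = 305.0
    insert_sd: float = 30.0
    base_error_rate: float = 0.005
    seed: int = 7

    def __post_init__(self) -> None:
        if self.insert_mean < self.read_len:
            raise ValueError("insert_mean must be >= read_len")
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must be in [0, 1]")


@dataclass(slots=True)
class ToolProfile:
    """How one assembler corrupts the truth.

    fragmentation_rate
        Probability a transcript is emitted as >= 2 overlapping fragments
        (overlaps >= 50 bp) instead of one whole contig.
    dropout_rate
        Probability a transcript is missing from this tool's assembly.
    noise_contigs
        Number of tool-private random contigs appended.
    substitution_rate
        Per-base substitution rate in emitted contigs.
    """

    fragmentation_rate: float = 0.3
    dropout_rate: float = 0.0
    noise_contigs: int = 20
    substitution_rate: float = 0.002

    def __post_init__(self) -> None:
        for p in (self.fragmentation_rate, self.dropout_rate, self.substitution_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("profile probabilities must be in [0, 1]")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, np.ndarray]:
    """Apply per-base substitutions; returns (sequence, error position mask)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    if mask.any():
        idx = np.flatnonzero(mask)
        shifts = rng.integers(1, 4, size=idx.size)
        lut = {65: 0, 67: 1, 71: 2, 84: 3, 78: 0}
        for pos, sh in zip(idx, shifts):
            arr[pos] = _BASES[(lut[arr[pos]] + sh) % 4]
    return arr.tobytes().decode("ascii"), mask


def simulate_transcriptome(config: SimConfig) -> tuple[list[Contig], np.ndarray]:
    """Sample the true transcriptome and its expression weights.

    Sequences are i.i.d. uniform bases at log-normal lengths; weights are
    log-normal, normalized to sum to 1. Deterministic under config.seed.
    """
    rng = _rng(config.seed, 0)
    lengths = []
    while len(lengths) < config.n_transcripts:
        draw = rng.lognormal(config.length_log_mean, config.length_log_sd)
        if config.min_transcript_len <= draw <= config.max_transcript_len:
            lengths.append(int(draw))
    transcripts = [
        Contig(f"tx{i:05d}", _random_seq(rng, L), "truth")
        for i, L in enumerate(lengths)
    ]
    weights = rng.lognormal(0.0, config.expression_log_sd, size=config.n_transcripts)
    weights /= weights.sum()
    return transcripts, weights


def simulate_reads(
    transcripts: Sequence[Contig],
    weights: np.ndarray,
    n_pairs: int,
    config: SimConfig,
) -> list[ReadPair]:
    """Sample paired-end reads from the weighted transcriptome.

    A transcript is chosen with probability proportional to
    weight x (length - read_len + 1) — expression-level-dependent coverage
    over the positions that can seat a fragment. The insert length is
    Normal(insert_mean, insert_sd) truncated to [read_len, transcript
    length]; mate 1 is the fragment's 5' read and mate 2 the reverse
    complement of its 3' read. Substitution errors occur at
    ``base_error_rate`` and are flagged by a low quality score.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    rng = _rng(config.seed, 1)
    eligible = np.array([len(t) >= config.read_len for t in transcripts])
    if not eligible.any():
        raise ValueError("no transcript can seat a fragment")
    positions = np.array(
        [max(0, len(t) - config.read_len + 1) for t in transcripts], dtype=np.float64
    )
    p = np.asarray(weights, dtype=np.float64) * positions
    p /= p.sum()

    choices = rng.choice(len(transcripts), size=n_pairs, p=p)
    pairs: list[ReadPair] = []
    for i, tidx in enumerate(choices):
        t = transcripts[tidx]
        L = len(t)
        insert = int(
            np.clip(rng.normal(config.insert_mean, config.insert_sd), config.read_len, L)
        )
        start = int(rng.integers(0, L - insert + 1))
        frag = t.seq[start : start + insert]
        rlen = min(config.read_len, insert)
        r1_seq, m1 = _substitute(rng, frag[:rlen], config.base_error_rate)
        r2_seq, m2 = _substitute(
            rng, reverse_complement(frag[-rlen:]), config.base_error_rate
        )
        q1 = "".join(QUAL_ERROR if e else QUAL_HIGH for e in m1)
        q2 = "".join(QUAL_ERROR if e else QUAL_HIGH for e in m2)
        rid = f"sim_{i:07d}_{t.id}"
        pairs.append(
            ReadPair(
                ReadRecord(rid, r1_seq, q1, mate_index=1),
                ReadRecord(rid, r2_seq, q2, mate_index=2),
            )
        )
    return pairs


def _fragment_points(
    rng: np.random.Generator, length: int
) -> list[tuple[int, int]]:
    """Overlapping fragment intervals covering [0, length)."""
    n_frag = 2 if length < 1500 or rng.random() < 0.5 else 3
    min_piece = 200
    if length < n_frag * min_piece + 100:
        n_frag = 2
    cuts = []
    lo = min_piece
    for _ in range(n_frag - 1):
        hi = length - min_piece * (n_frag - 1 - len(cuts))
        if lo >= hi:
            break
        cuts.append(int(rng.integers(lo, hi)))
        lo = cuts[-1] + min_piece
    if not cuts:
        return [(0, length)]
    intervals = []
    prev = 0
    for c in cuts:
        ov = int(rng.integers(50, 121))
        intervals.append((prev, min(length, c + ov)))
        prev = c
    intervals.append((prev, length))
    return intervals


def simulate_tool_assemblies(
    transcripts: Sequence[Contig],
    profiles: Sequence[tuple[str, ToolProfile]],
    seed: int,
) -> tuple[list[tuple[SourceLabel, list[Contig]]], dict[str, str]]:
    """Emit one corrupted assembly per tool plus the ground-truth map.

    Per tool, each transcript is dropped with probability ``dropout_rate``;
    otherwise it is emitted whole or (with probability
    ``fragmentation_rate``, for transcripts long enough to split) as
    overlapping fragments, with substitutions at ``substitution_rate`` and
    a random orientation flip per contig. ``noise_contigs`` random
    sequences are appended. The truth map sends every contig id to its
    source transcript id or to "noise".
    """
    if not profiles:
        raise ValueError("simulate_tool_assemblies: no tool profiles")
    assemblies: list[tuple[SourceLabel, list[Contig]]] = []
    truth: dict[str, str] = {}
    for pidx, (tool, profile) in enumerate(profiles):
        rng = _rng(seed, 100 + pidx)
        label = SourceLabel(tool, "sim")
        contigs: list[Contig] = []
        for t in transcripts:
            if rng.random() < profile.dropout_rate:
                continue
            fragment = (
                len(t) >= 500 and rng.random() < profile.fragmentation_rate
            )
            pieces = _fragment_points(rng, len(t)) if fragment else [(0, len(t))]
            for j, (s, e) in enumerate(pieces):
                seq, _ = _substitute(rng, t.seq[s:e], profile.substitution_rate)
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                cid = f"{tool}.{t.id}.f{j}"
                contigs.append(Contig(cid, seq, label))
                truth[cid] = t.id
        for j in range(profile.noise_contigs):
            length = int(rng.integers(250, 1501))
            cid = f"{tool}.noise.{j}"
            contigs.append(Contig(cid, _random_seq(rng, length), label))
            truth[cid] = "noise"
        assemblies.append((label, contigs))
    return assemblies, truth


def simulate_core_genes(
    transcripts: Sequence[Contig], n_genes: int, seed: int
) -> list[Contig]:
    """Pick internal windows of random transcripts as a synthetic core set.

    Each "core gene" is a contiguous 60-90% window of a distinct
    transcript (at least 200 bp), standing in for the coding sequence a
    real core-gene catalog would provide.
    """
    if not 0 < n_genes <= len(transcripts):
        raise ValueError("n_genes must be in (0, n_transcripts]")
    rng = _rng(seed, 200)
    chosen = rng.permutation(len(transcripts))[:n_genes]
    genes: list[Contig] = []
    for tidx in sorted(chosen):
        t = transcripts[tidx]
        frac = rng.uniform(0.6, 0.9)
        glen = max(200, int(len(t) * frac))
        glen = min(glen, len(t))
        start = int(rng.integers(0, len(t) - glen + 1))
        genes.append(Contig(f"core.{t.id}", t.seq[start : start + glen], "core"))
    return genes
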