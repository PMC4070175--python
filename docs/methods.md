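# Methods

## Scope and design

The package implements the desk-scale consensus workflow for de novo
transcriptome assembly evaluation. The de novo assemblers themselves
(de Bruijn graph construction, bubble resolution, scaffolding) are
deliberately out of scope: assemblies enter the pipeline as labeled FASTA
files, or are emulated by the simulator. What the package owns is
everything around them — read QC, subsampling, the evaluation metrics,
redundancy removal, mapping-based validation, the completeness proxy, and
the consensus merge with provenance.

## Read quality control

**Trimming.** Each Phred+33 quality character is converted to an error
probability e = 10^(−q/10). With limit ℓ (default 0.05), the running total
s(i) = max(0, s(i−1) + (ℓ − e(i))) is computed base by base; the retained
window starts at the first positive value of the final positive run and
ends at the position of the maximum of s. When the maximum is attained at
several positions the *last* one is used — the choice that retains the
most sequence; the window start is then the beginning of the positive run
containing that end. The recurrence is evaluated literally and
sequentially so that any independent re-implementation of the same
description produces bit-identical windows. Reads are discarded when
nothing is retained, when the window is shorter than 20 bp, or when it
contains more than 2 ambiguous (N) bases.

**Duplicates.** A pair is a duplicate when the ordered tuple
(mate-1 sequence, mate-2 sequence) matches a previously seen pair exactly;
an orphan when its sequence matches exactly. No reverse-complement
collapsing and no quality comparison: exact sequence equality is the
minimal reproducible definition, and the first occurrence is kept.

**Length filter.** After duplicate removal only reads strictly longer
than 50 bp are kept. A pair with one failing mate is broken and the
surviving mate becomes an orphan; the stage accounting (pairs, orphans,
sum at raw / trimmed / after-duplicates / after-length) therefore always
balances.

**Subsampling** uses `numpy.random.Generator` (PCG64) permutation — a
named, seedable algorithm recorded in the result — and operates on intact
pairs only; orphans are never subsampled. The unselected complement is the
validation read set for RMBT.

## Metrics and k selection

N50 is the community-standard convention: the largest length L present in
the assembly such that contigs of length ≥ L sum to at least half the
total. Assembly statistics are computed over non-redundant contigs
strictly longer than 200 bp, and "long" transcripts are strictly > 1 kb.
Mean length is computed after the > 200 bp filter.

"Maximize N50 while keeping the total assembly length as long as
possible" is operationalized as a Pareto filter with a tunable retention
fraction f (default 0.90): candidates with total length ≥ f · (best total)
are eligible, and the eligible candidate with the highest N50 wins, ties
going to the smaller k (lower k favors lowly expressed transcripts, so it
is the conservative tie-break). f is exposed in the configuration because
no exact rule exists for this trade-off.

## Redundancy removal

Greedy longest-first clustering in the style of cd-hit-est: contigs are
visited in decreasing length order (input order on ties, for determinism)
and removed when their identity to any retained longer representative
exceeds the threshold (default 0.99). Identity is defined over the
*shorter* sequence: the best infix (free-end-gap) alignment of the shorter
sequence inside the longer one, computed with edlib edit distance, so that
exact containment scores 1.0 and is always collapsed. Both strands are
compared, since de novo transcript orientation is arbitrary. When the two
sequences have equal length the infix alignment is evaluated in both
directions (it is direction-asymmetric: free end gaps apply to the target
only) and the higher identity is used, keeping the measure symmetric.

The word-count prefilter is exact-safe: by the q-gram lemma, identity
above threshold t over a shorter length L implies at least
(L − w + 1) − d·w shared w-mers (d the corresponding edit-distance bound,
w = 10 by default), so alignments are skipped only when the shared-word
count proves they cannot matter. Prefiltered and exhaustive clustering
therefore return identical results, which the test suite verifies.

## RMBT (reads mapped back to transcripts)

The external end-to-end mapper is replaced by an auditable model of the
same yes/no question: a read maps if the *entire* read aligns ungapped,
without clipping, on either strand of some transcript with at most
⌊0.04 · read length⌋ mismatches. Candidate placements come from a
pigeonhole seed scheme — the read is cut into (budget + 1) disjoint
segments, so any placement within budget matches at least one segment
exactly; segment hits in an exact k-mer index (k = min(22, L/(budget+1)))
enumerate every such placement, making the seeded mapper provably
equivalent to an all-offsets scan (also verified against one in the
tests). Reads too short to carry enough segments fall back to the full
scan. Among hits the minimum-mismatch one wins (ties: transcript id, then
position); multi-mappers count once; mates count individually, since the
metric is defined per read. A SAM adapter (`rmbt_from_sam`) accepts an
external mapper's output instead (mapped = primary record without flag
0x4), for use with real data.

Gapped and spliced alignment are deliberately excluded: the metric is a
validity check, and on substitution-dominated short-read data the
ungapped model changes almost nothing while keeping the implementation
fully checkable.

## Core-gene completeness proxy

The HMM-plus-gene-prediction machinery of core-gene pipelines is out of
scope; the proxy preserves the metric's role. For each core gene
(user-supplied nucleotide sequences) the best *single-transcript*
local-alignment coverage at ≥ 95% identity is computed
(Bio.Align.PairwiseAligner, local mode, match 1 / mismatch −2 / gap open
−3 / extend −1, both strands). Coverage ≥ 70% (the conventional
full-length cutoff of such tools) is *complete*, ≥ 30% *partial*, below
that *absent*; the reported partial percentage includes complete genes,
so partial ≥ complete always. Coverage is never stitched across
transcripts — "complete" means one intact gene-length transcript. A
shared-12-mer prefilter (either strand) skips gene/transcript pairs that
cannot produce a meaningful ≥ 95%-identity alignment; candidates are
aligned in decreasing shared-word order so a perfect hit short-circuits
the rest. The 30% partial cutoff and 95% identity floor are declared
defaults of the proxy, not reconstructions of any tool's internals.

## Consensus merging and robust contigs

Contigs from all input assemblies are pooled under namespaced ids
(`tool_k|original-id`) so provenance survives merging. Overlap detection
finds the best *ungapped* placement of one contig against another
(either orientation): all diagonals are scored exhaustively when the
length product is small (≤ 2·10⁶), else only diagonals sharing an exact
16-mer are scored — identical in the low-divergence regime merging
targets, where true overlaps always contain exact 16-mer runs. An overlap
is accepted at ≥ 40 bp and ≥ 90% identity, mirroring the documented
defaults of the classical overlap-layout assembler this step follows.
Gapped overlap handling is omitted: constituent divergence in this
workflow is substitution-dominated (assembler base-call differences), and
an indel-bearing overlap would fail the identity floor rather than be
mis-merged.

Accepted overlaps connect contigs into components; each component is laid
out breadth-first from its longest member by composing pairwise
offset/orientation constraints (first placement wins on conflicts —
random-sequence templates make conflicts vanishingly rare), and the
consensus takes the majority base per column with ties resolved by the
longest constituent. Unmerged contigs become singlets. Every input contig
appears in exactly one merged contig's constituent list (conservation,
tested).

A merged contig is **robust** when its constituents come from at least
`min_tools` (default 3) distinct tool names — tools, not assemblies, so
two k-values of one tool do not qualify. A strict mode instead requires
constituents from every input assembly. After robust filtering the > 200
bp and 99%-identity redundancy rules are re-applied, so reported robust
statistics are over non-redundant sequences.

## Simulation: what it emulates and what it does not

The generator reproduces the structural features the pipeline's logic
depends on: log-normal transcript lengths truncated to [200, 10,000] bp
(median ≈ 1 kb), log-normal expression weights, paired 100 bp reads with
insert ~ Normal(305, 30) truncated to the feasible range, per-base
substitution errors (default 0.5%) marked by low quality (Q5) against a
Q40 background, and per-tool assembly corruption: dropout, fragmentation
into ≥ 200 bp pieces overlapping by 50-120 bp, per-contig random
orientation, 0.2% substitutions, and tool-private random noise contigs.
Sampling probability is weight × (positions that can seat a fragment),
i.e. expression-and-length-proportional coverage.

It does **not** model GC/hexamer/positional bias, splicing or isoforms,
PCR duplicates, indels, chimeras, or homology between transcripts
(sequences are i.i.d. uniform bases). Passing tests therefore demonstrate
the correctness of the algorithms under clean, repeat-free conditions —
not performance on biological repeat structure or isoform complexity,
where real assemblies and real mappers face their hard cases. The
standard fixture (500 transcripts, 50,000 pairs, three tools, 50 core
genes) was sized so the full pipeline runs in a few minutes on one CPU
while still exercising every stage at realistic per-transcript coverage
(~10×).

## Numerical and degenerate-input choices

- Trimming uses sequential float accumulation (not a vectorized
  refactoring) so results are bit-reproducible against the recurrence's
  definition; quality characters below '!' are rejected.
- Phred+33 is assumed; Phred+64 input is re-encoded only when explicitly
  requested, never auto-detected.
- Empty inputs raise errors at the operation that defines them (empty
  length multiset for N50, empty gene set, zero reads for a percentage);
  filters that can legitimately empty an assembly raise only when
  statistics are requested of an empty result.
- All randomness flows from one top-level seed through named
  `numpy.random.SeedSequence` streams; reports are byte-identical across
  re-runs, and no iteration order in any hot path depends on Python
  string hashing.

## Known limitations

- The merger's ungapped overlap model will not merge constituents that
  differ by indels; such contigs survive as separate (possibly
  non-robust) sequences rather than producing a wrong consensus.
- The completeness proxy measures nucleotide coverage, not protein-level
  orthology; scores on real data are not numerically comparable to
  HMM-based pipelines, only analogous in role.
- The native mapper is substitution-only and end-to-end; spliced or
  clipped alignments require the SAM adapter with an external mapper.
- Merging is quadratic in candidate pairs per component and intended for
  up to ~10⁴-10⁵ pooled contigs, not whole mammalian-scale multi-million
  contig pools.
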