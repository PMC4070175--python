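import numpy as np
import pytest

from txome_consensus.consensus import (
    MergeParams,
    SourceLabel,
    find_overlap,
    merge_assemblies,
    robust_filter,
)
from txome_consensus.seqio import Contig, reverse_complement

from conftest import random_seq


class TestFindOverlap:
    def test_suffix_prefix_overlap(self, rng):
        x, y, z = random_seq(rng, 200), random_seq(rng, 60), random_seq(rng, 200)
        ov = find_overlap(x + y, y + z)
        assert ov is not None
        assert ov.length == 60 and ov.identity == 1.0
        assert ov.orientation == 1 and ov.offset == 200

    def test_containment(self, rng):
        a = random_seq(rng, 500)
        ov = find_overlap(a, a[100:300])
        assert ov is not None and ov.containment
        assert ov.offset == 100 and ov.identity == 1.0

    def test_reverse_complement_orientation(self, rng):
        x, y, z = random_seq(rng, 150), random_seq(rng, 80), random_seq(rng, 100)
        # b reverse-complemented reads y + z, dovetailing with a = x + y
        ov = find_overlap(x + y, reverse_complement(y + z))
        assert ov is not None and ov.orientation == -1
        assert ov.length == 80 and ov.offset == 150

    def test_random_pairs_never_overlap(self, rng):
        """Spurious >= 40 bp @ >= 90% identity between unrelated 300-mers
        has negligible probability: expect zero hits over 1000 pairs."""
        hits = 0
        for _ in range(1000):
            a, b = random_seq(rng, 300), random_seq(rng, 300)
            if find_overlap(a, b) is not None:
                hits += 1
        assert hits == 0

    def test_below_min_overlap_rejected(self, rng):
        x, y = random_seq(rng, 200), random_seq(rng, 30)
        assert find_overlap(x + y, y + random_seq(rng, 200)) is None

    def test_seeded_path_matches_exhaustive(self, rng):
        for _ in range(50):
            x = random_seq(rng, int(rng.integers(100, 400)))
            y = random_seq(rng, int(rng.integers(45, 120)))
            a, b = x + y, y + random_seq(rng, 150)
            exhaustive = find_overlap(a, b, exhaustive=True)
            seeded = find_overlap(a, b, exhaustive=False)
            assert (exhaustive.offset, exhaustive.length) == (
                seeded.offset, seeded.length
            )


def _labels(*tools):
    return [SourceLabel(t, "sim") for t in tools]


class TestMergeAssemblies:
    def test_identical_contig_three_tools(self, rng):
        seq = random_seq(rng, 400)
        assemblies = [
            (lab, [Contig("c", seq)]) for lab in _labels("A", "B", "C")
        ]
        merged = merge_assemblies(assemblies)
        assert len(merged) == 1
        (m,) = merged
        assert m.n_tools == 3 and len(m.constituents) == 3
        assert m.seq == seq

    def test_unique_contig_is_singlet(self, rng):
        assemblies = [
            (SourceLabel("A", 21), [Contig("c1", random_seq(rng, 300))]),
            (SourceLabel("B", 35), [Contig("c2", random_seq(rng, 300))]),
        ]
        merged = merge_assemblies(assemblies)
        assert len(merged) == 2
        assert all(len(m.constituents) == 1 and m.n_tools == 1 for m in merged)

    def test_template_reconstruction_across_three_tools(self, rng):
        """Two overlapping fragments (tools A, B) plus the full template
        (tool C) merge into one contig whose consensus equals the template."""
        template = random_seq(rng, 900)
        assemblies = [
            (SourceLabel("A", "sim"), [Contig("left", template[:520])]),
            (SourceLabel("B", "sim"), [Contig("right", template[460:])]),
            (SourceLabel("C", "sim"), [Contig("full", template)]),
        ]
        merged = merge_assemblies(assemblies)
        assert len(merged) == 1
        (m,) = merged
        assert m.n_tools == 3
        assert m.seq == template

    def test_consensus_majority_overrules_minority_error(self, rng):
        template = random_seq(rng, 400)
        corrupt = list(template)
        corrupt[200] = {"A": "C", "C": "G", "G": "T", "T": "A"}[corrupt[200]]
        assemblies = [
            (SourceLabel("A", "sim"), [Contig("c", template)]),
            (SourceLabel("B", "sim"), [Contig("c", template)]),
            (SourceLabel("C", "sim"), [Contig("c", "".join(corrupt))]),
        ]
        (m,) = merge_assemblies(assemblies)
        assert m.seq == template

    def test_constituent_conservation(self, rng):
        template = random_seq(rng, 1000)
        assemblies = []
        for tool in ("A", "B", "C"):
            contigs = [
                Contig(f"{tool}.l", template[:600]),
                Contig(f"{tool}.r", template[550:]),
                Contig(f"{tool}.noise", random_seq(rng, 350)),
            ]
            assemblies.append((SourceLabel(tool, "sim"), contigs))
        merged = merge_assemblies(assemblies)
        total_constituents = sum(len(m.constituents) for m in merged)
        assert total_constituents == 9
        ids = [c.contig_id for m in merged for c in m.constituents]
        assert len(set(ids)) == 9  # each input contig appears exactly once

    def test_reverse_complement_fragment_still_merges(self, rng):
        template = random_seq(rng, 700)
        assemblies = [
            (SourceLabel("A", "sim"), [Contig("f", template[:400])]),
            (SourceLabel("B", "sim"), [Contig("r", reverse_complement(template[340:]))]),
        ]
        (m,) = merge_assemblies(assemblies)
        assert len(m.constituents) == 2
        assert m.seq in (template, reverse_complement(template))


class TestRobustFilter:
    def _merged(self, rng):
        template = random_seq(rng, 600)
        assemblies = [
            (lab, [Contig("shared", template)]) for lab in _labels("A", "B", "C")
        ]
        assemblies[0][1].append(Contig("private", random_seq(rng, 300)))
        return merge_assemblies(assemblies)

    def test_three_tool_contig_retained_singlet_dropped(self, rng):
        merged = self._merged(rng)
        robust = robust_filter(merged, min_tools=3)
        assert len(robust) == 1 and robust[0].n_tools == 3

    def test_min_tools_one_keeps_everything(self, rng):
        merged = self._merged(rng)
        assert robust_filter(merged, 1) == merged

    def test_monotone_decreasing_in_min_tools(self, rng):
        merged = self._merged(rng)
        sizes = [len(robust_filter(merged, k)) for k in (1, 2, 3, 4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_tools_not_assemblies_counted(self, rng):
        seq = random_seq(rng, 500)
        # same tool at two k values: still a single tool
        assemblies = [
            (SourceLabel("A", 21), [Contig("c", seq)]),
            (SourceLabel("A", 35), [Contig("c", seq)]),
        ]
        merged = merge_assemblies(assemblies)
        assert len(merged) == 1 and merged[0].n_tools == 1
        assert robust_filter(merged, 3) == []

    def test_strict_mode_requires_every_assembly(self, rng):
        seq = random_seq(rng, 500)
        labels = [SourceLabel("A", 21), SourceLabel("B", 35), SourceLabel("C", 25)]
        assemblies = [(lab, [Contig("c", seq)]) for lab in labels[:2]]
        assemblies.append((labels[2], [Contig("other", random_seq(rng, 400))]))
        merged = merge_assemblies(assemblies)
        assert robust_filter(merged, require_labels=labels) == []
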