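import numpy as np
import pytest

from txome_consensus.qc import (
    TrimParams,
    length_keep_filter,
    remove_duplicates,
    run_qc,
    subsample_pairs,
    trim_interval,
    trim_read,
)
from txome_consensus.seqio import ReadPair, ReadRecord

from conftest import random_seq


def brute_force_trim(error_probs, limit):
    """Literal sequential simulation of the cumulative (limit - error)
    recurrence: clamp at zero, end at the last maximum, start at the
    beginning of the final positive run containing the end."""
    s = 0.0
    series = []
    for e in error_probs:
        s = max(0.0, s + (limit - e))
        series.append(s)
    smax = max(series)
    if smax <= 0.0:
        return None
    end = max(i for i, v in enumerate(series) if v == smax)
    start = end
    while start > 0 and series[start - 1] > 0.0:
        start -= 1
    return (start + 1, end + 1)


def _pair(seq1, seq2, q="I"):
    return ReadPair(
        ReadRecord("p", seq1, q * len(seq1), 1), ReadRecord("p", seq2, q * len(seq2), 2)
    )


class TestTrimInterval:
    def test_clean_read_kept_whole(self):
        assert trim_interval([0.01] * 10, 0.05) == (1, 10)

    def test_hopeless_read_discarded(self):
        assert trim_interval([0.9, 0.9, 0.9], 0.05) is None

    def test_interior_window(self):
        # running total: 0, 0.04, 0.08, 0 -> window covers bases 2..3
        assert trim_interval([0.5, 0.01, 0.01, 0.5], 0.05) == (2, 3)

    def test_tie_at_maximum_takes_last(self):
        # two identical positive runs separated by a clamp: the running
        # total attains its maximum at positions 3 and 7; the later run wins
        e = [0.01, 0.01, 0.01, 1.0, 0.01, 0.01, 0.01]
        assert trim_interval(e, 0.05) == (5, 7)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trim_interval([], 0.05)

    def test_matches_brute_force_recurrence(self, rng):
        for _ in range(1000):
            n = int(rng.integers(20, 151))
            quals = rng.integers(2, 41, size=n)
            e = 10.0 ** (-quals / 10.0)
            assert trim_interval(e, 0.05) == brute_force_trim(e, 0.05)

    def test_trim_never_extends_and_is_contiguous(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 80))
            e = rng.uniform(0.0, 1.0, size=n)
            iv = trim_interval(e, 0.05)
            if iv is not None:
                start, end = iv
                assert 1 <= start <= end <= n


class TestTrimRead:
    def test_short_window_discarded(self):
        # 19 good bases behind a wall of bad ones -> below min length 20
        read = ReadRecord("r", "A" * 25, "$" * 6 + "I" * 19)
        assert trim_read(read, TrimParams()) is None

    def test_ambiguity_filter(self):
        good = "I" * 30
        read3 = ReadRecord("r", "ACGNNTAC" + "N" + "A" * 21, good)
        assert trim_read(read3, TrimParams()) is None  # 3 Ns
        read2 = ReadRecord("r", "ACGNNTAC" + "A" * 22, good)
        kept = trim_read(read2, TrimParams())
        assert kept is not None and kept.seq.count("N") == 2

    def test_quality_slice_matches_sequence_slice(self):
        qual = "$$$" + "I" * 40 + "$$$"
        read = ReadRecord("r", "A" * 46, qual)
        kept = trim_read(read, TrimParams())
        assert kept.seq == "A" * 40
        assert kept.qual == "I" * 40


class TestDuplicates:
    def test_pair_level_duplicate_removed(self):
        a = _pair("AAAA" * 20, "CCCC" * 20)
        b = _pair("AAAA" * 20, "CCCC" * 20)
        pairs, orphans = remove_duplicates([a, b], [])
        assert pairs == [a]

    def test_single_mate_match_not_duplicate(self):
        a = _pair("AAAA" * 20, "CCCC" * 20)
        b = _pair("AAAA" * 20, "GGGG" * 20)
        pairs, _ = remove_duplicates([a, b], [])
        assert len(pairs) == 2

    def test_idempotent(self, rng):
        pairs = [
            _pair(random_seq(rng, 60), random_seq(rng, 60)) for _ in range(30)
        ] * 2
        orphans = [ReadRecord(f"o{i}", random_seq(rng, 60), "I" * 60) for i in range(10)]
        once = remove_duplicates(pairs, orphans)
        twice = remove_duplicates(*once)
        assert once == twice
        assert len(once[0]) == 30


class TestLengthKeep:
    def test_strictly_greater(self):
        orphan = ReadRecord("o", "A" * 50, "I" * 50)
        _, orphans = length_keep_filter([], [orphan], 50)
        assert orphans == []

    def test_broken_pair_produces_orphan(self):
        p = _pair("A" * 60, "C" * 45)
        pairs, orphans = length_keep_filter([p], [], 50)
        assert pairs == [] and len(orphans) == 1
        assert orphans[0].seq == "A" * 60

    def test_all_long_unchanged(self, rng):
        pairs = [_pair(random_seq(rng, 100), random_seq(rng, 100)) for _ in range(5)]
        out_pairs, out_orphans = length_keep_filter(pairs, [], 50)
        assert out_pairs == pairs and out_orphans == []


class TestQCConservation:
    def test_stage_counts_balance(self, rng):
        pairs = []
        for i in range(200):
            n1 = int(rng.integers(30, 120))
            n2 = int(rng.integers(30, 120))
            q1 = "".join(chr(33 + int(q)) for q in rng.integers(2, 41, size=n1))
            q2 = "".join(chr(33 + int(q)) for q in rng.integers(2, 41, size=n2))
            pairs.append(
                ReadPair(
                    ReadRecord(f"p{i}", random_seq(rng, n1), q1, 1),
                    ReadRecord(f"p{i}", random_seq(rng, n2), q2, 2),
                )
            )
        # inject guaranteed duplicates
        pairs += pairs[:10]
        res = run_qc(pairs)
        counts = res.report.counts
        for stage in counts.values():
            assert stage["sum"] == stage["paired_reads"] + stage["orphans"]
            assert stage["paired_reads"] % 2 == 0
        order = ["raw", "trimmed", "after_dup_all", "after_dup_gt_keep"]
        sums = [counts[s]["sum"] for s in order]
        assert all(a >= b for a, b in zip(sums, sums[1:]))
        # outputs match the final stage's books
        assert counts["after_dup_gt_keep"]["paired_reads"] == 2 * len(res.pairs)
        assert counts["after_dup_gt_keep"]["orphans"] == len(res.orphans)

    def test_pair_break_balances_orphans(self):
        # mate 2 entirely low quality -> pair breaks, one orphan appears
        p = ReadPair(
            ReadRecord("p", "A" * 80, "I" * 80, 1),
            ReadRecord("p", "C" * 80, "#" * 80, 2),
        )
        res = run_qc([p])
        assert res.report.counts["trimmed"] == {
            "paired_reads": 0, "orphans": 1, "sum": 1
        }


class TestSubsample:
    def _pairs(self, rng, n):
        return [_pair(random_seq(rng, 60), random_seq(rng, 60)) for _ in range(n)]

    def test_full_and_empty_subsets(self, rng):
        pairs = self._pairs(rng, 10)
        full = subsample_pairs(pairs, 10, 1)
        assert full.selected == pairs and full.unselected == []
        empty = subsample_pairs(pairs, 0, 1)
        assert empty.selected == [] and empty.unselected == pairs

    def test_partition_and_determinism(self, rng):
        pairs = self._pairs(rng, 100)
        a = subsample_pairs(pairs, 40, 99)
        b = subsample_pairs(pairs, 40, 99)
        assert a.selected == b.selected
        assert len(a.selected) == 40 and len(a.unselected) == 60
        sel_ids = {id(p) for p in a.selected}
        assert sel_ids.isdisjoint(id(p) for p in a.unselected)
        c = subsample_pairs(pairs, 40, 100)
        assert c.selected != a.selected

    def test_oversized_request_rejected(self, rng):
        with pytest.raises(ValueError):
            subsample_pairs(self._pairs(rng, 3), 4, 1)

    def test_uniformity_binomial(self, rng):
        """Each of 10 pairs selected with frequency ~0.1 under n=1 draws."""
        pairs = self._pairs(rng, 10)
        counts = np.zeros(10)
        for trial in range(10_000):
            res = subsample_pairs(pairs, 1, trial)
            counts[pairs.index(res.selected[0])] += 1
        # binomial(10000, 0.1): sd ~ 30; allow 3 sigma
        assert np.all(np.abs(counts - 1000) < 3 * 30 + 1)
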