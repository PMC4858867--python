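"""Interval union, tiling, density and GC kernels against a per-base oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromotile import (
    ConfigError,
    Feature,
    SequenceRecord,
    auto_window,
    density,
    gc_track,
    merge,
    select_track,
    tile,
    window_coverage,
)
from helpers import bitmap, oracle_total_coverage, oracle_window_coverage

# strategy: interval lists on a smallish sequence
LENGTH = 10_000
intervals_st = st.lists(
    st.tuples(st.integers(1, LENGTH), st.integers(1, 500)).map(
        lambda p: (p[0], min(p[0] + p[1] - 1, LENGTH))
    ),
    max_size=120,
)


def feats(pairs, strand="plus", seqid="chr1", ftype="gene"):
    return [Feature(seqid, "t", ftype, s, e, strand) for s, e in pairs]


class TestMerge:
    def test_overlap_union(self):
        assert merge([(100, 200), (150, 250)]).intervals == [(100, 250)]

    def test_identity(self):
        assert merge([(10, 20)]).intervals == [(10, 20)]

    def test_touching_intervals_become_one(self):
        assert merge([(1, 5), (6, 9)]).intervals == [(1, 9)]

    def test_empty_input(self):
        assert merge([]).intervals == [] and merge([]).total_coverage == 0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(intervals_st)
    def test_total_coverage_matches_bitmap_oracle(self, pairs):
        assert merge(pairs).total_coverage == oracle_total_coverage(pairs, LENGTH)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(intervals_st)
    def test_idempotent_and_canonical(self, pairs):
        once = merge(pairs)
        twice = merge(once.intervals)
        assert once.intervals == twice.intervals
        starts, ends = once.starts, once.ends
        assert np.all(ends >= starts)
        # strictly separated: no overlap and no touching runs left
        assert np.all(starts[1:] > ends[:-1] + 1)

    def test_500_random_intervals_against_bitmap(self):
        rng = np.random.default_rng(42)
        s = rng.integers(1, 10_000, size=500)
        pairs = [(int(a), int(min(a + l, 10_000))) for a, l in zip(s, rng.integers(1, 400, 500))]
        assert merge(pairs).total_coverage == oracle_total_coverage(pairs, 10_000)


class TestTile:
    def test_truncated_final_window(self):
        w = tile("c", 100, 40)
        assert [(x.start, x.end) for x in w] == [(1, 40), (41, 80), (81, 100)]

    def test_exact_tiling(self):
        w = tile("c", 80, 40)
        assert [(x.start, x.end) for x in w] == [(1, 40), (41, 80)]

    def test_window_larger_than_sequence_gives_single_window(self):
        w = tile("c", 50, 1000)
        assert [(x.start, x.end) for x in w] == [(1, 50)]

    def test_region_tiling_is_one_based_inclusive(self):
        from chromotile import Region

        w = tile("c", 10_000, 100, Region("c", 200, 450))
        assert [(x.start, x.end) for x in w] == [(201, 300), (301, 400), (401, 450)]

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(1, 50_000), st.integers(1, 9_000))
    def test_spans_sum_to_length_and_disjoint(self, L, W):
        wins = tile("c", L, W)
        assert sum(w.span for w in wins) == L
        assert wins[0].start == 1 and wins[-1].end == L
        for a, b in zip(wins, wins[1:]):
            assert b.start == a.end + 1
        assert all(w.span <= W for w in wins)


class TestDensity:
    def test_full_coverage_is_100_either_rounding(self):
        mi = merge([(1, 40_000)])
        wins = tile("c", 40_000, 40_000)
        for r in ("floor", "ceil"):
            assert density(mi, wins, "gene", r).values == [100]

    def test_sub_percent_rounding(self):
        # 200 covered bases in a 40 kb window: raw 0.5 %
        mi = merge([(1001, 1200)])
        wins = tile("c", 40_000, 40_000)
        assert density(mi, wins, "gene", "ceil").values == [1]
        assert density(mi, wins, "gene", "floor").values == [0]

    def test_unknown_rounding_rejected(self):
        with pytest.raises(ConfigError, match="rounding"):
            density(merge([(1, 5)]), tile("c", 10, 10), "gene", "round")

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(intervals_st, st.integers(50, 4000))
    def test_value_brackets_bitmap_oracle_raw(self, pairs, W):
        mi = merge(pairs)
        wins = tile("c", LENGTH, W)
        fl = density(mi, wins, "gene", "floor").values
        ce = density(mi, wins, "gene", "ceil").values
        cov = oracle_window_coverage(pairs, wins, LENGTH)
        for f, c, cv, w in zip(fl, ce, cov, wins):
            raw = 100.0 * cv / w.span
            assert f == int(np.floor(raw)) and c == int(np.ceil(raw))
            assert 0 <= f <= c <= 100 and c - f <= 1

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(intervals_st, st.integers(100, 3000), st.randoms(use_true_random=False))
    def test_invariant_under_feature_order(self, pairs, W, rnd):
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        wins = tile("c", LENGTH, W)
        assert (
            density(merge(pairs), wins, "g").values
            == density(merge(shuffled), wins, "g").values
        )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(intervals_st, st.integers(100, 3000))
    def test_conservation_across_windows(self, pairs, W):
        mi = merge(pairs)
        wins = tile("c", LENGTH, W)
        assert int(window_coverage(mi, wins).sum()) == mi.total_coverage

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(intervals_st, intervals_st, st.integers(100, 3000))
    def test_fused_coverage_bounds(self, plus_pairs, minus_pairs, W):
        wins = tile("c", LENGTH, W)
        fs = feats(plus_pairs, "plus") + feats(minus_pairs, "minus")
        by_label = {
            label: window_coverage(merge(fs_, track=label, seqid="chr1"), wins)
            for label, fs_ in select_track(fs, "all")
        }
        spans = np.array([w.span for w in wins])
        assert np.all(by_label["fused"] >= np.maximum(by_label["plus"], by_label["minus"]))
        assert np.all(
            by_label["fused"] <= np.minimum(spans, by_label["plus"] + by_label["minus"])
        )


class TestSelectTrack:
    def test_track_counts_per_mode(self):
        fs = feats([(1, 10)], "plus") + feats([(20, 30)], "minus")
        for mode, n in (("minus", 1), ("plus", 1), ("both", 2), ("fused", 1), ("all", 3)):
            assert len(select_track(fs, mode)) == n

    def test_all_mode_partition(self):
        fs = feats([(1, 10)], "plus") + feats([(20, 30)], "minus")
        got = {label: len(f) for label, f in select_track(fs, "all")}
        assert got == {"minus": 1, "plus": 1, "fused": 2}

    def test_unstranded_routes_to_fused_only(self):
        fs = feats([(i, i + 5) for i in (1, 10, 20, 30, 40)], "unstranded")
        ((label, got),) = select_track(fs, "fused")
        assert label == "fused" and len(got) == 5
        assert select_track(fs, "both") == [("minus", []), ("plus", [])]

    def test_unknown_mode(self):
        with pytest.raises(ConfigError, match="minus, plus, both, fused, all"):
            select_track([], "reverse")


class TestGcTrack:
    def _rec(self, seq):
        return SequenceRecord("c", len(seq), seq)

    @pytest.mark.parametrize(
        "seq, expect",
        [("GGGGCCCC", 100), ("ATATATAT", 0), ("ACGTNNNN", 50)],
    )
    def test_known_compositions(self, seq, expect):
        rec = self._rec(seq)
        wins = tile("c", len(seq), len(seq))
        assert gc_track(rec, wins).values == [expect]

    def test_all_n_window_reports_zero(self):
        rec = self._rec("NNNN")
        assert gc_track(rec, tile("c", 4, 4)).values == [0]

    def test_lowercase_counted(self):
        rec = self._rec("acgtACGT")
        assert gc_track(rec, tile("c", 8, 8)).values == [50]

    def test_missing_sequence_is_an_error(self):
        from chromotile import ChromotileError

        with pytest.raises(ChromotileError, match="FASTA"):
            gc_track(SequenceRecord("c", 100), tile("c", 100, 10))

    def test_matches_python_count_on_random_sequence(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGTN"), size=5000))
        rec = self._rec(seq)
        wins = tile("c", 5000, 137)
        got = gc_track(rec, wins, "floor").values
        for w, v in zip(wins, got):
            sub = seq[w.start - 1 : w.end]
            denom = sum(sub.count(b) for b in "ACGT")
            expect = 0 if denom == 0 else (100 * (sub.count("G") + sub.count("C"))) // denom
            assert v == expect


class TestAutoWindow:
    def test_exact_division(self):
        assert auto_window([1_000_000], 1000) == 1000

    def test_ceiling(self):
        assert auto_window([1_000_001], 1001, 1) == 1001

    def test_no_room_is_config_error(self):
        with pytest.raises(ConfigError, match="height"):
            auto_window([100], 100, 100)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(1, 10**9), min_size=1, max_size=8),
        st.integers(10, 5000),
        st.integers(0, 400),
    )
    def test_longest_sequence_fits_budget(self, lengths, max_px, chrome):
        if max_px - chrome <= 0:
            return
        W = auto_window(lengths, max_px, chrome)
        assert -(-max(lengths) // W) <= max_px - chrome
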