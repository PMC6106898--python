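import numpy as np
import pytest

from rohaudit.cnv_regions import (
    build_cnvr,
    clean_calls,
    cnvr_set,
    cnvr_summary,
    consensus_cnvr,
    discretize_segment,
    filter_samples_by_call_count,
)
from rohaudit.core import CnvCall, Cnvr, GenomicInterval


def call(sample, start, end, state=-1, caller="a", chrom="1"):
    return CnvCall(sample, GenomicInterval(chrom, start, end), state, caller)


class TestDiscretize:
    @pytest.mark.parametrize(
        "mean,expected",
        [(0.31, 1), (-0.45, -1), (0.29, 0), (0.30, 1), (-0.30, -1), (0.0, 0), (-0.29, 0)],
    )
    def test_threshold_boundaries(self, mean, expected):
        assert discretize_segment(mean) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            discretize_segment(float("nan"))


class TestCleanCalls:
    def test_short_gap_merged(self):
        # lengths 100 and 80, gap 20 < 0.2 * 180 = 36
        out = clean_calls([call("s", 0, 100), call("s", 120, 200)])
        assert [(c.interval.start, c.interval.end) for c in out] == [(0, 200)]

    def test_long_gap_not_merged(self):
        # lengths 100 and 80, gap 50 >= 36
        out = clean_calls([call("s", 0, 100), call("s", 150, 230)])
        assert len(out) == 2

    def test_book_ended_merged(self):
        out = clean_calls([call("s", 0, 100), call("s", 100, 150)])
        assert len(out) == 1

    def test_cascading_merge_reaches_fixed_point(self):
        # merging the first two creates a long call that then absorbs the third
        calls = [call("s", 0, 1000), call("s", 1150, 2150), call("s", 2500, 2600)]
        # gap2 = 350 >= 0.2*(1000+100)=220 alone, but 350 < 0.2*(2150+100)=450 merged
        out = clean_calls(calls)
        assert [(c.interval.start, c.interval.end) for c in out] == [(0, 2600)]

    def test_idempotent(self, rng):
        calls = []
        for s in ("s1", "s2"):
            pos = 0
            for _ in range(20):
                pos += int(rng.integers(10, 400))
                start = pos
                pos += int(rng.integers(50, 500))
                calls.append(call(s, start, pos, state=int(rng.choice([-1, 1]))))
        once = clean_calls(calls)
        assert clean_calls(once) == once

    def test_different_states_never_merged(self):
        out = clean_calls([call("s", 0, 100, state=-1), call("s", 110, 200, state=1)])
        assert len(out) == 2


class TestSampleFilter:
    @staticmethod
    def calls_with_counts(counts):
        out = []
        for j, k in enumerate(counts):
            for i in range(k):
                out.append(call(f"s{j}", 1000 * i, 1000 * i + 100))
        return out

    def test_single_outlier_excluded(self):
        kept, excluded, fence = filter_samples_by_call_count(
            self.calls_with_counts([10, 10, 10, 10, 100])
        )
        assert excluded == ["s4"]
        assert fence == pytest.approx(10.0)
        assert {c.sample_id for c in kept} == {"s0", "s1", "s2", "s3"}

    def test_equal_counts_none_excluded(self):
        _, excluded, _ = filter_samples_by_call_count(self.calls_with_counts([5, 5, 5, 5]))
        assert excluded == []

    def test_type7_quartile_fence(self):
        # counts (1,2,3,4): Q1 = 1.75, Q3 = 3.25 -> fence = 3.25 + 1.5*1.5 = 5.5
        _, excluded, fence = filter_samples_by_call_count(self.calls_with_counts([1, 2, 3, 4]))
        assert fence == pytest.approx(5.5)
        assert excluded == []

    def test_fewer_than_four_samples_pass_through(self):
        calls = self.calls_with_counts([3, 4, 50])
        with pytest.warns(UserWarning):
            kept, excluded, fence = filter_samples_by_call_count(calls)
        assert kept == calls and excluded == [] and np.isnan(fence)


class TestBuildCnvr:
    def test_mixed_states_make_both(self):
        regions = build_cnvr([call("s1", 0, 100, -1), call("s2", 50, 150, 1)])
        assert regions == [Cnvr(GenomicInterval("1", 0, 150), "both", 2, "a")]

    def test_single_loss_call(self):
        (r,) = build_cnvr([call("s1", 10, 20, -1)])
        assert r.category == "loss" and r.n_samples == 1

    def test_book_ended_calls_stay_separate(self):
        regions = build_cnvr([call("s1", 0, 100, -1), call("s2", 100, 200, -1)])
        assert len(regions) == 2

    def test_output_disjoint_and_covers_union(self, rng):
        calls = []
        for _ in range(50):
            start = int(rng.integers(0, 95_000))
            calls.append(
                call(f"s{rng.integers(5)}", start, start + int(rng.integers(1, 5_000)),
                     state=int(rng.choice([-1, 1])))
            )
        regions = build_cnvr(calls)
        cover = np.zeros(100_000, dtype=bool)
        for c in calls:
            cover[c.interval.start : c.interval.end] = True
        region_cover = np.zeros(100_000, dtype=bool)
        for r in regions:
            assert not region_cover[r.interval.start : r.interval.end].any()  # disjoint
            region_cover[r.interval.start : r.interval.end] = True
        assert np.array_equal(cover, region_cover)


class TestConsensus:
    def c(self, start, end, category, n=1, chrom="1"):
        return Cnvr(GenomicInterval(chrom, start, end), category, n, "x")

    def test_shared_loss(self):
        out = consensus_cnvr([self.c(0, 100, "loss")], [self.c(50, 150, "loss")])
        assert out == [Cnvr(GenomicInterval("1", 50, 100), "loss", 1, "consensus")]

    def test_disjoint_sets_empty(self):
        assert consensus_cnvr([self.c(0, 100, "loss")], [self.c(200, 300, "loss")]) == []

    def test_both_parent_dominates(self):
        out = consensus_cnvr([self.c(0, 100, "both")], [self.c(80, 120, "gain")])
        assert out == [Cnvr(GenomicInterval("1", 80, 100), "both", 1, "consensus")]

    def test_disagreeing_parents_become_both(self):
        out = consensus_cnvr([self.c(0, 100, "loss")], [self.c(50, 150, "gain")])
        assert out[0].category == "both"

    def test_consensus_coverage_bounded_by_parents(self, rng):
        def random_set():
            regions = []
            pos = 0
            for _ in range(20):
                pos += int(rng.integers(100, 2000))
                start = pos
                pos += int(rng.integers(100, 3000))
                regions.append(self.c(start, pos, str(rng.choice(["loss", "gain", "both"]))))
            return regions

        a, b = random_set(), random_set()
        cons = consensus_cnvr(a, b)
        cov = lambda rs: sum(r.interval.length for r in rs)
        assert cov(cons) <= min(cov(a), cov(b))


def test_cnvr_summary_shape():
    regions = [
        Cnvr(GenomicInterval("1", 0, 1_000_000), "loss", 3, "a"),
        Cnvr(GenomicInterval("1", 2_000_000, 2_500_000), "gain", 1, "a"),
    ]
    table = cnvr_summary(regions, genome_length_bp=100_000_000)
    overall = table[table["category"] == "overall"].iloc[0]
    assert overall["n"] == 2
    assert overall["coverage_mb"] == pytest.approx(1.5)
    assert overall["coverage_pct"] == pytest.approx(1.5)
    assert set(table["category"]) == {"loss", "gain", "overall"}
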