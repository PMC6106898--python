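import numpy as np
import pytest

from rohaudit.artefact_audit import (
    PlacementError,
    _place_islands,
    classify_island,
    coverage_summary,
    permutation_test,
)
from rohaudit.cnv_regions import Cnvr
from rohaudit.core import GenomicInterval, IntervalSet, intersect_length
from .conftest import make_map


def cnvr(start, end, category, chrom="1"):
    return Cnvr(GenomicInterval(chrom, start, end), category, 1, "x")


class TestIntersectLength:
    def test_simple_overlap(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        b = IntervalSet([GenomicInterval("chr1", 5, 20)])
        assert intersect_length(a, b)["total"] == 5

    def test_disjoint(self):
        a = IntervalSet([GenomicInterval("1", 0, 10)])
        b = IntervalSet([GenomicInterval("1", 20, 30)])
        assert intersect_length(a, b)["total"] == 0

    def test_matches_bitmap_oracle(self, rng):
        for _ in range(20):
            def random_set():
                ivs = []
                for _ in range(50):
                    s = int(rng.integers(0, 99_000))
                    ivs.append(GenomicInterval("1", s, s + int(rng.integers(1, 2000))))
                return IntervalSet(ivs)

            a, b = random_set(), random_set()
            bm_a = np.zeros(101_000, dtype=bool)
            bm_b = np.zeros(101_000, dtype=bool)
            for iv_ in a:
                bm_a[iv_.start : iv_.end] = True
            for iv_ in b:
                bm_b[iv_.start : iv_.end] = True
            assert intersect_length(a, b)["total"] == int(np.sum(bm_a & bm_b))


class TestClassifyIsland:
    @pytest.fixture()
    def mm(self):
        return make_map(list(range(1000, 200_001, 1000)))

    def test_loss_only_island_is_artefact(self, mm):
        island = GenomicInterval("1", 10_000, 30_000)
        audit = classify_island(island, [cnvr(20_000, 40_000, "loss")], IntervalSet(), 5000, mm)
        assert audit.label == "loss" and audit.is_artefact
        assert audit.overlap_bp["loss"] == 10_000

    def test_clean_island(self, mm):
        island = GenomicInterval("1", 10_000, 30_000)
        audit = classify_island(island, [], IntervalSet(), 5000, mm)
        assert audit.label == "clean" and not audit.is_artefact
        assert audit.mean_imd == pytest.approx(1000.0)

    def test_all_three_flags(self, mm):
        island = GenomicInterval("1", 10_000, 60_000)
        cnvrs = [cnvr(15_000, 20_000, "loss"), cnvr(30_000, 35_000, "gain")]
        gaps = IntervalSet([GenomicInterval("1", 50_000, 55_000)])
        audit = classify_island(island, cnvrs, gaps, 5000, mm)
        assert audit.label == "gap+loss+gain" and audit.is_artefact

    def test_both_cnvr_sets_loss_and_gain(self, mm):
        island = GenomicInterval("1", 10_000, 30_000)
        audit = classify_island(island, [cnvr(12_000, 15_000, "both")], IntervalSet(), 5000, mm)
        assert audit.has_loss and audit.has_gain

    def test_high_mean_imd_flags_gap_without_overlap(self, mm):
        island = GenomicInterval("1", 10_000, 30_000)
        audit = classify_island(island, [], IntervalSet(), fence_bp=999, marker_map=mm)
        assert audit.has_gap and audit.label == "gap"

    def test_gain_only_not_artefact_by_default_but_configurable(self, mm):
        island = GenomicInterval("1", 10_000, 30_000)
        audit = classify_island(island, [cnvr(12_000, 15_000, "gain")], IntervalSet(), 5000, mm)
        assert audit.label == "gain" and not audit.is_artefact
        audit2 = classify_island(
            island, [cnvr(12_000, 15_000, "gain")], IntervalSet(), 5000, mm, gain_as_artefact=True
        )
        assert audit2.is_artefact

    def test_island_with_one_marker_fails_imd_check(self):
        mm = make_map([1000, 500_000])
        island = GenomicInterval("1", 900, 2000)
        with pytest.warns(UserWarning):
            audit = classify_island(island, [], IntervalSet(), 5000, mm)
        assert audit.has_gap


class TestCoverageSummary:
    def test_all_clean(self, rng):
        mm = make_map(list(range(1000, 100_001, 1000)))
        audits = [
            classify_island(GenomicInterval("1", 10_000, 20_000), [], IntervalSet(), 5000, mm)
        ]
        table = coverage_summary(audits)
        overall = table[table["label"] == "overall affected"].iloc[0]
        assert overall["n_islands"] == 0 and overall["pct_of_island_coverage"] == 0.0

    def test_loss_percentage_arithmetic(self):
        mm = make_map(list(range(1000, 30_000_001, 1000)))
        loss_island = GenomicInterval("1", 0, 10_000_000)
        clean_island = GenomicInterval("1", 15_000_000, 25_000_000)
        audits = [
            classify_island(loss_island, [cnvr(0, 1_000_000, "loss")], IntervalSet(), 5000, mm),
            classify_island(clean_island, [], IntervalSet(), 5000, mm),
        ]
        table = coverage_summary(audits)
        loss_row = table[table["label"] == "loss"].iloc[0]
        assert loss_row["coverage_mb"] == pytest.approx(10.0)
        assert loss_row["pct_of_island_coverage"] == pytest.approx(50.0)


class TestPermutationTest:
    def test_cnvr_covering_whole_chromosome_is_invariant(self):
        islands = IntervalSet([GenomicInterval("1", 40_000_000, 42_000_000)])
        cnvr_all = IntervalSet([GenomicInterval("1", 0, 100_000_000)])
        res = permutation_test(islands, cnvr_all, {"1": 100_000_000}, n_perm=200, seed=1)
        assert res.empirical_pvalue == 1.0
        assert res.rohr_mean_bp == pytest.approx(res.rohd_bp)

    def test_empty_cnvr_gives_zero_everywhere(self):
        islands = IntervalSet([GenomicInterval("1", 0, 2_000_000)])
        res = permutation_test(islands, IntervalSet(), {"1": 100_000_000}, n_perm=100, seed=2)
        assert res.rohd_bp == 0 and res.rohr_mean_bp == 0.0

    def test_planted_enrichment_is_significant(self):
        # islands sit exactly on CNVRs that cover 1% of a 300 Mb genome
        islands = IntervalSet(
            [GenomicInterval("1", 50_000_000, 51_000_000),
             GenomicInterval("2", 70_000_000, 72_000_000)]
        )
        cnvr = IntervalSet(
            [GenomicInterval("1", 50_000_000, 51_000_000),
             GenomicInterval("2", 70_000_000, 72_000_000)]
        )
        res = permutation_test(
            islands, cnvr, {"1": 150_000_000, "2": 150_000_000}, n_perm=1000, seed=3
        )
        assert res.rohd_bp == 3_000_000
        assert res.rohd_bp > 10 * res.rohr_mean_bp
        assert res.empirical_pvalue <= 0.01
        assert res.t_pvalue < 1e-10

    def test_infeasible_packing_names_chromosome(self):
        islands = IntervalSet(
            [GenomicInterval("7", 0, 4_000_000), GenomicInterval("7", 5_000_000, 9_000_000)]
        )
        with pytest.raises(PlacementError, match="7"):
            permutation_test(islands, IntervalSet(), {"7": 9_000_000}, n_perm=10, seed=4)

    def test_placement_respects_spacing_and_lengths(self, rng):
        lengths = np.array([1_000_000, 2_000_000, 500_000])
        starts = _place_islands(lengths, 50_000_000, 500, 1_000_000, rng, "1")
        assert starts.shape == (500, 3)
        for row in starts:
            order = np.argsort(row)
            s = row[order]
            l = lengths[order]
            assert np.all(s + l <= 50_000_000)
            assert np.all(s[1:] - (s[:-1] + l[:-1]) > 1_000_000)

    def test_confidence_interval_brackets_mean(self):
        islands = IntervalSet([GenomicInterval("1", 10_000_000, 11_000_000)])
        cnvr = IntervalSet([GenomicInterval("1", i * 10_000_000, i * 10_000_000 + 2_000_000)
                            for i in range(10)])
        res = permutation_test(islands, cnvr, {"1": 100_000_000}, n_perm=500, seed=5)
        assert res.ci_low_bp <= res.rohr_mean_bp <= res.ci_high_bp
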