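import numpy as np
import pytest

from rohaudit.core import IntervalSet, MISSING
from rohaudit.genotype_qc import hwe_pvalue
from rohaudit.island_calling import marker_inbreeding_levels
from rohaudit.roh_detection import detect_roh, merge_roh
from rohaudit.synthetic_data import (
    GenerationError,
    Layout,
    PlannedCnv,
    PlannedGap,
    PlannedIsland,
    SimConfig,
    default_layout,
    emit_baf_lrr,
    simulate_dataset,
)

SMALL = SimConfig(
    n_chromosomes=3,
    chrom_length_bp=20_000_000,
    n_samples=20,
    with_intensities=False,
    seed=5,
)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        a = simulate_dataset(SMALL)
        b = simulate_dataset(SMALL)
        assert np.array_equal(a.dataset.genotypes, b.dataset.genotypes)
        assert np.array_equal(a.haplotypes.alleles, b.haplotypes.alleles)
        assert a.calls_a == b.calls_a and a.calls_b == b.calls_b
        assert a.truth == b.truth

    def test_different_seeds_differ(self):
        import dataclasses

        a = simulate_dataset(SMALL)
        b = simulate_dataset(dataclasses.replace(SMALL, seed=6))
        assert not np.array_equal(a.dataset.genotypes, b.dataset.genotypes)


class TestBackgroundHwe:
    def test_background_markers_in_hwe(self):
        config = SimConfig(
            n_chromosomes=1,
            chrom_length_bp=3_000_000,
            n_samples=500,
            with_intensities=False,
            seed=9,
        )
        res = simulate_dataset(config, layout=Layout((), (), ()))
        g = res.dataset.genotypes
        pvals = np.array(
            [
                hwe_pvalue(int(np.sum(row == 0)), int(np.sum(row == 1)), int(np.sum(row == 2)))
                for row in g
            ]
        )
        assert np.mean(pvals > 0.001) >= 0.99

    def test_genotypes_consistent_with_haplotypes_outside_deletions(self):
        res = simulate_dataset(SMALL, layout=Layout((), (), ()))
        expected = (res.haplotypes.alleles[0::2] + res.haplotypes.alleles[1::2]).T
        assert np.array_equal(res.dataset.genotypes, expected)


class TestEmission:
    def test_noiseless_diploid_het(self):
        config = SimConfig(lrr_sd=0.0, baf_sd=0.0)
        rng = np.random.default_rng(0)
        baf, lrr = emit_baf_lrr(2, 1, config, rng)
        assert (baf, lrr) == (0.5, 0.0)

    def test_noiseless_double_deletion_has_uniform_baf(self):
        config = SimConfig(lrr_sd=0.0, baf_sd=0.0)
        rng = np.random.default_rng(0)
        bafs = [emit_baf_lrr(0, 0, config, rng)[0] for _ in range(200)]
        lrrs = {emit_baf_lrr(0, 0, config, rng)[1] for _ in range(5)}
        assert lrrs == {config.lrr_mu[0]}
        assert 0.2 < np.std(bafs) < 0.4  # uniform, not clustered

    def test_hemizygous_deletion_baf_at_extremes(self):
        config = SimConfig(lrr_sd=0.0, baf_sd=0.0)
        rng = np.random.default_rng(0)
        assert emit_baf_lrr(1, 0, config, rng)[0] == 0.0
        assert emit_baf_lrr(1, 2, config, rng)[0] == 1.0

    def test_monte_carlo_lrr_means(self):
        config = SimConfig()
        rng = np.random.default_rng(12)
        n = 10_000
        for state in range(5):
            _, lrr = emit_baf_lrr(np.full(n, state), np.full(n, 2), config, rng)
            se = config.lrr_sd / np.sqrt(n)
            assert abs(lrr.mean() - config.lrr_mu[state]) < 3 * se

    def test_state_means_ordered_and_separated(self):
        config = SimConfig()
        gaps = np.diff(config.lrr_mu)
        assert np.all(gaps >= 2 * config.lrr_sd)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            emit_baf_lrr(5, 0, SimConfig(), np.random.default_rng(0))


class TestTruthConsistency:
    def test_planted_labels_present(self, default_sim):
        labels = {t.label for t in default_sim.truth.planted_islands}
        assert labels == {"clean", "loss_artefact", "gain_affected", "gap_artefact"}

    def test_gap_inside_gap_island_and_marker_free(self, default_sim):
        (gap,) = default_sim.truth.planted_gaps
        gap_islands = [t for t in default_sim.truth.planted_islands if t.label == "gap_artefact"]
        assert any(
            t.interval.start < gap.start and gap.end < t.interval.end for t in gap_islands
        )
        pos = default_sim.dataset.marker_map.positions(gap.chrom)
        inside = (pos > gap.start) & (pos <= gap.end)
        assert not inside.any()
        assert gap.length > 50_000  # far above any background spacing

    def test_deletion_carriers_recorded_homozygous(self, default_sim):
        ds = default_sim.dataset
        for t in default_sim.truth.planted_cnv:
            if t.state != -1:
                continue
            lo, hi = ds.marker_map.markers_in(t.interval)
            sl = ds.marker_map.chrom_slice(t.interval.chrom)
            block = ds.genotypes[sl.start + lo : sl.start + hi][:, list(t.carriers)]
            assert not np.any(block == 1)

    def test_full_carrier_fraction_gives_level_one(self):
        import dataclasses

        config = dataclasses.replace(SMALL, island_carrier_fraction=1.0)
        layout = Layout(
            islands=(PlannedIsland(0, 5_000_000, 1_100_000, "clean"),),
            cnvs=(),
            gaps=(),
        )
        res = simulate_dataset(config, layout)
        merged = merge_roh(detect_roh(res.dataset))
        for sid in res.dataset.sample_ids:
            merged.setdefault(sid, IntervalSet())
        levels = marker_inbreeding_levels(merged, res.dataset.marker_map)
        (t,) = res.truth.planted_islands
        lo, hi = res.dataset.marker_map.markers_in(t.interval)
        assert np.all(levels[lo:hi] == 1.0)

    def test_zero_deletion_carriers_impossible_but_fraction_respected(self, default_sim):
        for t in default_sim.truth.planted_cnv:
            assert len(t.carriers) >= 1

    def test_caller_b_calls_are_subset_with_jitter(self, default_sim):
        # every caller call points back to a planted CNV (same chromosome, state,
        # overlapping coordinates)
        truth = default_sim.truth.planted_cnv
        for call in default_sim.calls_a + default_sim.calls_b:
            assert any(
                t.interval.chrom == call.interval.chrom
                and t.state == call.state
                and t.interval.overlaps(call.interval)
                for t in truth
            )

    def test_layout_collision_raises(self):
        layout = Layout(
            islands=(
                PlannedIsland(0, 5_000_000, 1_100_000, "clean"),
                PlannedIsland(0, 5_500_000, 1_100_000, "clean"),
            ),
            cnvs=(),
            gaps=(),
        )
        with pytest.raises(GenerationError, match="collides"):
            simulate_dataset(SMALL, layout)

    def test_island_too_close_to_chromosome_end_raises(self):
        layout = Layout(
            islands=(PlannedIsland(0, 19_500_000, 1_100_000, "clean"),),
            cnvs=(),
            gaps=(),
        )
        with pytest.raises(GenerationError):
            simulate_dataset(SMALL, layout)

    def test_default_layout_scales_with_genome(self):
        layout = default_layout(SimConfig())
        assert len(layout.islands) == 4
        assert all(i.length_bp >= 1_000_000 for i in layout.islands)
        # total island extent stays below 1% of the genome so the
        # 99th-percentile cutoff falls in the background
        total = sum(i.length_bp for i in layout.islands)
        genome = SimConfig().n_chromosomes * SimConfig().chrom_length_bp
        assert total < 0.01 * genome
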