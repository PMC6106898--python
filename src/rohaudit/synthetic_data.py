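"""Synthetic genotype / intensity / CNV-call / haplotype fixtures with known truth.

The generator emulates the data situation the audit is built for:

* background markers drawn independently in Hardy-Weinberg equilibrium
  at mid-range allele frequencies (SNP arrays ascertain common variants);
* ROH islands planted as a single high-frequency shared haplotype (the
  per-marker major alleles): every chromosome copy independently carries
  the island haplotype with probability sqrt(island_carrier_fraction),
  so the expected fraction of samples homozygous for it equals
  island_carrier_fraction while every island marker stays exactly in
  Hardy-Weinberg proportions (random union of haplotypes) and therefore
  survives the HWE quality filter at the nominal rate;
* hemizygous deletions whose carriers are *recorded homozygous* (the
  mistyping mechanism by which copy loss manufactures false ROH) while
  their intensities follow the one-copy emission model: depressed LRR,
  BAF pushed to the extremes;
* copy gains with elevated LRR and unchanged genotypes;
* marker-free coverage gaps wider than any background spacing;
* two caller-specific corruptions of the planted CNV truth (independent
  drop probabilities, boundary jitter for the second caller) so that
  consensus logic is exercised.

Each planted island is flanked by a short "wall" of markers that are
heterozygous in every island carrier (at an overall heterozygote
fraction that still passes the HWE filter). Walls emulate the
polymorphic flanks that terminate real ROH and make the planted
truth exactly recoverable: detected ROH clip at the island edges
instead of leaking into the background by the heterozygote allowance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    CnvCall,
    GenomicInterval,
    GenotypeDataset,
    IntensityTable,
    IntervalSet,
    MarkerMap,
    MISSING,
)
from .haplotype_diversity import PhasedHaplotypes

ISLAND_LABELS = ("clean", "loss_artefact", "gain_affected", "gap_artefact")


class GenerationError(RuntimeError):
    """Invalid planted layout (collisions, out-of-range placements)."""


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters. Defaults define the package's study conditions."""

    n_chromosomes: int = 3
    chrom_length_bp: int = 160_000_000
    n_samples: int = 30
    mean_marker_spacing_bp: int = 5_000
    allele_freq_range: tuple[float, float] = (0.35, 0.65)
    missing_rate: float = 0.0
    island_carrier_fraction: float = 0.42
    cnv_carrier_fraction: float = 0.3
    wall_markers: int = 5
    wall_het_fraction: float = 0.734
    lrr_mu: tuple[float, ...] = (-3.5, -0.55, 0.0, 0.35, 0.65)
    lrr_sd: float = 0.15
    baf_sd: float = 0.03
    caller_a_drop: float = 0.1
    caller_b_drop: float = 0.2
    caller_b_jitter_markers: int = 2
    with_intensities: bool = True
    seed: int = 2026

    def __post_init__(self):
        for name in ("n_chromosomes", "chrom_length_bp", "n_samples", "mean_marker_spacing_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("island_carrier_fraction", "cnv_carrier_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must satisfy 0 < lo <= hi < 1")
        if list(self.lrr_mu) != sorted(self.lrr_mu):
            raise ValueError("lrr_mu must be ordered by copy state")


@dataclass(frozen=True)
class PlannedIsland:
    chrom_index: int
    start_bp: int
    length_bp: int
    label: str

    def __post_init__(self):
        if self.label not in ISLAND_LABELS:
            raise ValueError(f"unknown island label {self.label!r}")


@dataclass(frozen=True)
class PlannedCnv:
    chrom_index: int
    start_bp: int
    length_bp: int
    state: int  # -1 loss, +1 gain


@dataclass(frozen=True)
class PlannedGap:
    chrom_index: int
    start_bp: int
    length_bp: int


@dataclass(frozen=True)
class Layout:
    islands: tuple[PlannedIsland, ...]
    cnvs: tuple[PlannedCnv, ...]  # off-island CNVs and gain CNVs inside gain islands
    gaps: tuple[PlannedGap, ...]


def default_layout(config: SimConfig) -> Layout:
    """The standard planted scenario: one island per label plus scattered CNVs.

    Placements are fixed fractions of the chromosome length, so the layout
    scales with the configured genome. Total island extent stays below 1%
    of the genome, leaving the 99th-percentile cutoff in the background of
    the marker-inbreeding distribution.
    """
    L = config.chrom_length_bp
    if config.n_chromosomes < 3:
        raise GenerationError("default layout needs at least 3 chromosomes")
    islands = (
        PlannedIsland(0, int(0.25 * L), 1_100_000, "clean"),
        PlannedIsland(1, int(0.25 * L), 1_100_000, "gain_affected"),
        PlannedIsland(1, int(0.60 * L), 1_300_000, "gap_artefact"),
        PlannedIsland(2, int(0.30 * L), 1_100_000, "loss_artefact"),
    )
    cnvs = (
        # gain CNV inside the gain-affected island
        PlannedCnv(1, int(0.25 * L) + 300_000, 500_000, +1),
        # scattered off-island CNVs (shorter than the minimum ROH length so
        # mistyped runs never reach the ROH detector's smallest class)
        PlannedCnv(0, int(0.50 * L), 300_000, -1),
        PlannedCnv(0, int(0.70 * L), 350_000, +1),
        PlannedCnv(1, int(0.10 * L), 250_000, -1),
        PlannedCnv(2, int(0.60 * L), 400_000, -1),
        PlannedCnv(2, int(0.80 * L), 300_000, +1),
    )
    gaps = (PlannedGap(1, int(0.60 * L) + 500_000, 250_000),)
    return Layout(islands=islands, cnvs=cnvs, gaps=gaps)


@dataclass(frozen=True)
class PlantedIslandTruth:
    interval: GenomicInterval
    label: str
    carriers: tuple[int, ...]


@dataclass(frozen=True)
class PlantedCnvTruth:
    interval: GenomicInterval
    state: int
    carriers: tuple[int, ...]


@dataclass(frozen=True)
class SyntheticTruth:
    planted_islands: tuple[PlantedIslandTruth, ...]
    planted_cnv: tuple[PlantedCnvTruth, ...]
    planted_gaps: tuple[GenomicInterval, ...]
    seed: int

    def island_set(self) -> IntervalSet:
        return IntervalSet(t.interval for t in self.planted_islands)


@dataclass
class SimResult:
    dataset: GenotypeDataset
    intensities: Optional[IntensityTable]
    haplotypes: PhasedHaplotypes
    calls_a: list[CnvCall]
    calls_b: list[CnvCall]
    truth: SyntheticTruth
    config: SimConfig


def _validate_layout(config: SimConfig, layout: Layout) -> None:
    margin = int(2.0 * config.wall_markers * 1.5 * config.mean_marker_spacing_bp)
    conflicts = []
    regions: list[tuple[str, int, int, int]] = []
    for isl in layout.islands:
        regions.append(("island", isl.chrom_index, isl.start_bp - margin, isl.start_bp + isl.length_bp + margin))
        if isl.start_bp - margin < 0 or isl.start_bp + isl.length_bp + margin > config.chrom_length_bp:
            conflicts.append(f"island at chrom {isl.chrom_index} too close to a chromosome end")
    for cnv in layout.cnvs:
        regions.append(("cnv", cnv.chrom_index, cnv.start_bp, cnv.start_bp + cnv.length_bp))
    for gap in layout.gaps:
        inside = any(
            isl.chrom_index == gap.chrom_index
            and isl.start_bp < gap.start_bp
            and gap.start_bp + gap.length_bp < isl.start_bp + isl.length_bp
            for isl in layout.islands
        )
        if not inside:
            regions.append(("gap", gap.chrom_index, gap.start_bp, gap.start_bp + gap.length_bp))
    for i, (kind_a, ca, sa, ea) in enumerate(regions):
        for kind_b, cb, sb, eb in regions[i + 1 :]:
            if kind_a == "cnv" and kind_b == "cnv":
                continue  # CNVs may overlap each other (CNVR "both" regions)
            if {kind_a, kind_b} == {"island", "cnv"}:
                # gain CNVs inside gain islands and the loss CNV defining a
                # loss island are intentional overlaps
                continue
            if ca == cb and sa < eb and sb < ea:
                conflicts.append(f"{kind_a} [{sa},{ea}) collides with {kind_b} [{sb},{eb}) on chrom {ca}")
    off_island_cnv_overlaps = [
        (cnv, isl)
        for cnv in layout.cnvs
        for isl in layout.islands
        if cnv.chrom_index == isl.chrom_index
        and cnv.start_bp < isl.start_bp + isl.length_bp
        and isl.start_bp < cnv.start_bp + cnv.length_bp
        and not (
            isl.label == "gain_affected"
            and cnv.state == +1
            and cnv.start_bp >= isl.start_bp
            and cnv.start_bp + cnv.length_bp <= isl.start_bp + isl.length_bp
        )
    ]
    for cnv, isl in off_island_cnv_overlaps:
        conflicts.append(
            f"planned CNV [{cnv.start_bp},{cnv.start_bp + cnv.length_bp}) collides with "
            f"{isl.label} island on chrom {cnv.chrom_index}"
        )
    if conflicts:
        raise GenerationError("layout conflicts: " + "; ".join(conflicts))


def emit_baf_lrr(copy_state, genotype, config: SimConfig, rng: np.random.Generator):
    """Draw (baf, lrr) from the copy-state emission model.

    LRR ~ Normal(mu[state], sd) with state means ordered from homozygous
    deletion (very low) to multi-copy gain (elevated). BAF centres depend
    on the state and the underlying genotype: a double deletion has no
    signal (uniform BAF); a hemizygous deletion is driven by the single
    remaining allele (extremes); diploid states sit near {0, 1/2, 1};
    three copies near {0, 1/3, 2/3, 1}; four copies near {0, 1/2, 1}
    for the balanced heterozygote.
    """
    state = np.asarray(copy_state)
    geno = np.broadcast_to(np.asarray(genotype), state.shape)
    if np.any((state < 0) | (state > 4)):
        raise ValueError("copy state must be in {0,1,2,3,4}")
    mu = np.asarray(config.lrr_mu, dtype=float)
    lrr = mu[state] + (rng.normal(0.0, config.lrr_sd, size=state.shape) if config.lrr_sd > 0 else 0.0)

    half = geno == 1
    b_allele = (geno == 2).astype(float)
    centre = np.where(half, 0.5, b_allele)
    # three copies: duplicated allele of a heterozygote picks 1/3 or 2/3
    third = np.where(rng.random(size=state.shape) < 0.5, 1.0 / 3.0, 2.0 / 3.0)
    centre = np.where((state == 3) & half, third, centre)
    noise = rng.normal(0.0, config.baf_sd, size=state.shape) if config.baf_sd > 0 else 0.0
    baf = np.clip(centre + noise, 0.0, 1.0)
    baf = np.where(state == 0, rng.random(size=state.shape), baf)
    if np.ndim(copy_state) == 0:
        return float(baf), float(lrr)
    return baf, lrr


def _snap(pos: np.ndarray, start_bp: int, end_bp: int) -> tuple[int, int]:
    """Chromosome-local indices of the first/last marker inside [start_bp, end_bp]."""
    a = int(np.searchsorted(pos, start_bp, side="left"))
    b = int(np.searchsorted(pos, end_bp, side="right")) - 1
    if b < a:
        raise GenerationError(f"no markers in planned region [{start_bp},{end_bp}]")
    return a, b


def simulate_dataset(config: SimConfig, layout: Optional[Layout] = None) -> SimResult:
    """Generate the full fixture set for one synthetic study."""
    if layout is None:
        layout = default_layout(config)
    _validate_layout(config, layout)
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"s{j + 1:03d}" for j in range(n)]

    chrom_names = [str(c + 1) for c in range(config.n_chromosomes)]
    all_chrom: list[str] = []
    all_ids: list[str] = []
    all_pos: list[np.ndarray] = []
    hap_blocks: list[np.ndarray] = []
    geno_blocks: list[np.ndarray] = []
    state_blocks: list[np.ndarray] = []
    truth_islands: list[PlantedIslandTruth] = []
    truth_cnvs: list[PlantedCnvTruth] = []
    truth_gaps: list[GenomicInterval] = []
    calls_a: list[CnvCall] = []
    calls_b: list[CnvCall] = []

    k_island = max(1, round(config.island_carrier_fraction * n))
    k_cnv = max(1, round(config.cnv_carrier_fraction * n))
    n_wall_het = min(n, round(config.wall_het_fraction * n))

    for c, chrom in enumerate(chrom_names):
        spacing = config.mean_marker_spacing_bp
        n_draw = int(config.chrom_length_bp / spacing * 1.3) + 10
        steps = rng.integers(max(1, spacing // 2), spacing + spacing // 2 + 1, size=n_draw)
        pos = np.cumsum(steps)
        pos = pos[pos <= config.chrom_length_bp].astype(np.int64)

        # carve marker-free coverage gaps
        for gap in layout.gaps:
            if gap.chrom_index != c:
                continue
            gs, ge = gap.start_bp, gap.start_bp + gap.length_bp
            inside = (pos > gs) & (pos <= ge)
            left = pos[pos <= gs]
            right = pos[pos > ge]
            if len(left) == 0 or len(right) == 0:
                raise GenerationError(f"gap [{gs},{ge}) has no flanking markers")
            truth_gaps.append(GenomicInterval(chrom, int(left[-1]), int(right[0]) - 1))
            pos = pos[~inside]

        m = len(pos)
        freq_lo, freq_hi = config.allele_freq_range
        q = rng.uniform(freq_lo, freq_hi, size=m)  # frequency of allele B (code 2)
        haps = (rng.random((2 * n, m)) < q).astype(np.int8)
        states = np.full((m, n), 2, dtype=np.int8)

        def wall_edit(a: int, b: int, carriers: np.ndarray) -> None:
            """Make flanking markers heterozygous in every carrier (plus fill)."""
            target = max(n_wall_het, len(carriers))
            het = list(carriers)
            for j in range(n):
                if len(het) >= target:
                    break
                if j not in set(het):
                    het.append(j)
            het_set = np.array(sorted(het[:target]))
            hom_set = np.array([j for j in range(n) if j not in set(het_set.tolist())])
            for widx in list(range(a - config.wall_markers, a)) + list(
                range(b + 1, b + 1 + config.wall_markers)
            ):
                if not 0 <= widx < m:
                    raise GenerationError(f"wall marker out of range on chrom {chrom}")
                haps[2 * het_set, widx] = 0
                haps[2 * het_set + 1, widx] = 1
                for i, j in enumerate(hom_set):
                    allele = np.int8(i % 2)
                    haps[2 * j, widx] = allele
                    haps[2 * j + 1, widx] = allele

        deletion_regions: list[tuple[int, int, np.ndarray]] = []

        for isl in layout.islands:
            if isl.chrom_index != c:
                continue
            a, b = _snap(pos, isl.start_bp, isl.start_bp + isl.length_bp)
            interval = GenomicInterval(chrom, int(pos[a]) - 1, int(pos[b]))
            if isl.label == "loss_artefact":
                carriers = np.sort(rng.choice(n, size=k_cnv, replace=False))
                deletion_regions.append((a, b, carriers))
                states[a : b + 1, carriers] = 1
                truth_cnvs.append(PlantedCnvTruth(interval, -1, tuple(int(x) for x in carriers)))
            else:
                # high-frequency shared haplotype under random mating: each
                # chromosome copy is the shared haplotype with probability h,
                # so hom-carriers ~ h^2 of samples and island markers stay in HWE
                h = float(np.sqrt(config.island_carrier_fraction))
                shared = (q[a : b + 1] > 0.5).astype(np.int8)  # per-marker major allele
                is_shared = rng.random(2 * n) < h
                haps[np.nonzero(is_shared)[0][:, None], np.arange(a, b + 1)[None, :]] = shared
                both = is_shared[0::2] & is_shared[1::2]
                carriers = np.nonzero(both)[0]
                if carriers.size == 0:
                    raise GenerationError(
                        f"{isl.label} island on chrom {chrom} has no homozygous carrier; "
                        "raise island_carrier_fraction"
                    )
            wall_edit(a, b, carriers)
            truth_islands.append(
                PlantedIslandTruth(interval, isl.label, tuple(int(x) for x in carriers))
            )

        for cnv in layout.cnvs:
            if cnv.chrom_index != c:
                continue
            a, b = _snap(pos, cnv.start_bp, cnv.start_bp + cnv.length_bp)
            interval = GenomicInterval(chrom, int(pos[a]) - 1, int(pos[b]))
            carriers = np.sort(rng.choice(n, size=k_cnv, replace=False))
            if cnv.state == -1:
                deletion_regions.append((a, b, carriers))
                states[a : b + 1, carriers] = 1
            else:
                states[a : b + 1, carriers] = 3
            truth_cnvs.append(PlantedCnvTruth(interval, cnv.state, tuple(int(x) for x in carriers)))

        geno = (haps[0::2] + haps[1::2]).T.astype(np.int8)  # (m, n); code = B-allele count
        # hemizygous mistyping: deletion carriers are recorded homozygous for
        # the remaining (first) haplotype
        for a, b, carriers in deletion_regions:
            geno[a : b + 1][:, carriers] = (2 * haps[2 * carriers, a : b + 1]).T

        # caller outputs from the planted truth
        chrom_cnvs = [t for t in truth_cnvs if t.interval.chrom == chrom]
        for t in chrom_cnvs:
            ia, ib = _snap(pos, t.interval.start + 1, t.interval.end)
            seg_mean = config.lrr_mu[1] if t.state == -1 else config.lrr_mu[3]
            for j in t.carriers:
                if rng.random() >= config.caller_a_drop:
                    calls_a.append(
                        CnvCall(sample_ids[j], t.interval, t.state, "callerA", seg_mean)
                    )
                if rng.random() >= config.caller_b_drop:
                    jit = config.caller_b_jitter_markers
                    ja = int(np.clip(ia + rng.integers(-jit, jit + 1), 0, m - 1))
                    jb = int(np.clip(ib + rng.integers(-jit, jit + 1), 0, m - 1))
                    if jb < ja:
                        ja, jb = jb, ja
                    iv = GenomicInterval(chrom, int(pos[ja]) - 1, int(pos[jb]))
                    calls_b.append(CnvCall(sample_ids[j], iv, t.state, "callerB", seg_mean))

        if config.missing_rate > 0:
            mask = rng.random(geno.shape) < config.missing_rate
            geno[mask] = MISSING

        all_chrom.extend([chrom] * m)
        all_ids.extend(f"snp_{chrom}_{i + 1}" for i in range(m))
        all_pos.append(pos)
        hap_blocks.append(haps)
        geno_blocks.append(geno)
        state_blocks.append(states)

    marker_map = MarkerMap(all_chrom, all_ids, np.concatenate(all_pos))
    genotypes = np.concatenate(geno_blocks, axis=0)
    haplotypes = np.concatenate(hap_blocks, axis=1)
    states_all = np.concatenate(state_blocks, axis=0)
    dataset = GenotypeDataset(marker_map, sample_ids, genotypes)
    phased = PhasedHaplotypes(marker_map, sample_ids, haplotypes)

    intensities = None
    if config.with_intensities:
        geno_true = (haplotypes[0::2] + haplotypes[1::2]).T
        baf, lrr = emit_baf_lrr(states_all, geno_true, config, rng)
        intensities = IntensityTable(marker_map, sample_ids, baf, lrr)

    truth = SyntheticTruth(
        planted_islands=tuple(truth_islands),
        planted_cnv=tuple(truth_cnvs),
        planted_gaps=tuple(truth_gaps),
        seed=config.seed,
    )
    return SimResult(dataset, intensities, phased, calls_a, calls_b, truth, config)


def write_fixture_dir(result: SimResult, outdir, with_intensities: bool = False) -> dict[str, str]:
    """Write every input format the pipeline reads, plus truth BED5 files."""
    import os

    from . import io_formats as io

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ped": os.path.join(outdir, "genotypes.ped"),
        "map": os.path.join(outdir, "genotypes.map"),
        "calls_a": os.path.join(outdir, "cnv_calls_callerA.tsv"),
        "calls_b": os.path.join(outdir, "cnv_calls_callerB.tsv"),
        "haplotypes": os.path.join(outdir, "haplotypes.tsv"),
        "truth_islands": os.path.join(outdir, "truth_islands.bed"),
        "truth_cnv": os.path.join(outdir, "truth_cnv.bed"),
        "truth_gaps": os.path.join(outdir, "truth_gaps.bed"),
        "config": os.path.join(outdir, "sim_config.txt"),
    }
    io.write_plink_text(result.dataset, paths["ped"], paths["map"])
    io.write_cnv_calls(result.calls_a, paths["calls_a"])
    io.write_cnv_calls(result.calls_b, paths["calls_b"])
    io.write_haplotypes(
        result.haplotypes.marker_map,
        result.haplotypes.sample_ids,
        result.haplotypes.alleles,
        paths["haplotypes"],
    )
    io.write_bed(
        [t.interval for t in result.truth.planted_islands],
        paths["truth_islands"],
        names=[t.label for t in result.truth.planted_islands],
        scores=[len(t.carriers) for t in result.truth.planted_islands],
    )
    io.write_bed(
        [t.interval for t in result.truth.planted_cnv],
        paths["truth_cnv"],
        names=["loss" if t.state == -1 else "gain" for t in result.truth.planted_cnv],
        scores=[len(t.carriers) for t in result.truth.planted_cnv],
    )
    io.write_bed(list(result.truth.planted_gaps), paths["truth_gaps"])
    with open(paths["config"], "w") as fh:
        for key, value in sorted(vars(result.config).items()):
            fh.write(f"{key}={value}\n")
    if with_intensities and result.intensities is not None:
        paths["intensities"] = os.path.join(outdir, "intensities.tsv")
        io.write_intensity_table(result.intensities, paths["intensities"])
    return paths
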