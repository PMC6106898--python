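"""End-to-end orchestration: QC -> ROH -> islands -> CNVR -> gaps -> audit -> diversity."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io_formats as io
from .artefact_audit import (
    IslandAudit,
    PermutationResult,
    audit_islands,
    audit_table,
    coverage_summary,
    permutation_test,
)
from .cnv_regions import (
    build_cnvr,
    clean_calls,
    cnvr_set,
    cnvr_summary,
    consensus_cnvr,
    filter_samples_by_call_count,
)
from .config import RunConfig
from .core import CnvCall, Cnvr, GenotypeDataset, IntervalSet
from .coverage_gaps import all_distances, gap_intervals, intermarker_distances, tukey_upper_fence
from .genotype_qc import apply_qc
from .haplotype_diversity import PhasedHaplotypes, block_table, compare_categories
from .island_calling import (
    Island,
    call_islands,
    island_set,
    island_threshold,
    islands_table,
    marker_inbreeding_levels,
)
from .roh_detection import detect_roh, f_roh, merge_roh

log = logging.getLogger("rohaudit")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    config: RunConfig
    qc_report: pd.DataFrame
    dataset: GenotypeDataset
    roh_by_sample: dict
    froh: dict[str, float]
    levels: np.ndarray
    cutoff: float
    islands: list[Island]
    cnvr_by_source: dict[str, list[Cnvr]]
    excluded_samples: dict[str, list[str]]
    fence_bp: float
    fence_detail: Optional[dict]
    gaps: IntervalSet
    audits: list[IslandAudit]
    coverage: pd.DataFrame
    permutations: dict[str, PermutationResult]
    blocks: Optional[pd.DataFrame]
    anova: Optional[pd.DataFrame]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return out
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(
    dataset: GenotypeDataset,
    calls_a: list[CnvCall],
    calls_b: Optional[list[CnvCall]],
    haplotypes: Optional[PhasedHaplotypes],
    config: RunConfig,
) -> PipelineResult:
    """Run every stage on in-memory inputs; see :func:`run_audit` for file I/O."""

    # --- QC ---------------------------------------------------------------
    @_stage("qc")
    def do_qc():
        return apply_qc(dataset, config.qc_thresholds())

    ds, qc_report = do_qc()
    log.info(
        "qc: %d/%d markers, %d/%d samples retained",
        ds.n_markers,
        dataset.n_markers,
        ds.n_samples,
        dataset.n_samples,
    )

    # --- ROH + F_ROH ------------------------------------------------------
    @_stage("roh")
    def do_roh():
        segments = detect_roh(ds, config.roh_classes)
        merged = merge_roh(segments)
        for sid in ds.sample_ids:  # samples with no ROH still count downstream
            merged.setdefault(sid, IntervalSet())
        denom = config.froh_denominator_bp or sum(
            ds.marker_map.chrom_span(c) for c in ds.marker_map.chromosomes()
        )
        froh = {sid: f_roh(ivs, denom) for sid, ivs in sorted(merged.items())}
        return merged, froh

    roh_by_sample, froh = do_roh()

    # --- islands ----------------------------------------------------------
    @_stage("islands")
    def do_islands():
        levels = marker_inbreeding_levels(roh_by_sample, ds.marker_map)
        cutoff = island_threshold(levels, config.island_percentile)
        islands = call_islands(levels, ds.marker_map, cutoff, config.island_min_markers)
        return levels, cutoff, islands

    levels, cutoff, islands = do_islands()
    log.info("islands: cutoff %.4f, %d islands", cutoff, len(islands))

    # --- CNVR -------------------------------------------------------------
    @_stage("cnvr")
    def do_cnvr():
        cnvr_by_source: dict[str, list[Cnvr]] = {}
        excluded: dict[str, list[str]] = {}
        for tag, calls in (("callerA", calls_a), ("callerB", calls_b)):
            if calls is None:
                continue
            cleaned = clean_calls(calls, config.call_merge_gap_fraction)
            if config.exclude_outlier_samples:
                cleaned, dropped, _fence = filter_samples_by_call_count(cleaned)
                excluded[tag] = dropped
            cnvr_by_source[tag] = build_cnvr(cleaned, tag)
        if config.consensus:
            if "callerA" not in cnvr_by_source or "callerB" not in cnvr_by_source:
                raise ValueError("consensus requested but both caller files are required")
            cnvr_by_source["consensus"] = consensus_cnvr(
                cnvr_by_source["callerA"], cnvr_by_source["callerB"]
            )
        return cnvr_by_source, excluded

    cnvr_by_source, excluded_samples = do_cnvr()

    # --- coverage gaps ----------------------------------------------------
    # gap structure is a property of the chip map, so by default it is
    # derived from the raw (pre-QC) marker map: QC-dropped markers must not
    # manufacture phantom gaps
    gap_map = dataset.marker_map if config.gaps_on_raw_map else ds.marker_map

    @_stage("gaps")
    def do_gaps():
        imd = intermarker_distances(gap_map)
        if config.fence_override_bp is not None:
            return float(config.fence_override_bp), None, gap_intervals(gap_map, config.fence_override_bp)
        fence = tukey_upper_fence(all_distances(imd))
        detail = {"q1": fence.q1, "q3": fence.q3, "fence_bp": fence.fence}
        return fence.fence, detail, gap_intervals(gap_map, fence.fence)

    fence_bp, fence_detail, gaps = do_gaps()

    # --- audit ------------------------------------------------------------
    @_stage("audit")
    def do_audit():
        source = config.cnvr_source
        if source not in cnvr_by_source:
            raise ValueError(f"cnvr_source {source!r} not available (have {sorted(cnvr_by_source)})")
        audits = audit_islands(
            islands, cnvr_by_source[source], gaps, fence_bp, gap_map, config.gain_as_artefact
        )
        coverage = coverage_summary(audits)
        permutations: dict[str, PermutationResult] = {}
        if islands:
            chrom_lengths = {
                c: ds.marker_map.chrom_span(c) for c in ds.marker_map.chromosomes()
            }
            isl_set = island_set(islands)
            rng = np.random.default_rng(config.seed)
            for tag in sorted(cnvr_by_source):
                permutations[tag] = permutation_test(
                    isl_set,
                    cnvr_set(cnvr_by_source[tag], config.permutation_categories),
                    chrom_lengths,
                    n_perm=config.n_permutations,
                    min_gap_bp=config.permutation_min_gap_bp,
                    seed=config.seed,
                    rng=rng,
                )
        return audits, coverage, permutations

    audits, coverage, permutations = do_audit()

    # --- haplotype diversity ----------------------------------------------
    @_stage("diversity")
    def do_diversity():
        if haplotypes is None or not audits:
            return None, None
        labelled = [(a.island, a.label) for a in audits]
        blocks = block_table(
            labelled,
            haplotypes,
            block_size=config.block_size_bp,
            min_markers=config.block_min_markers,
            breed=config.breed,
        )
        anova = compare_categories(blocks) if blocks["category"].nunique() > 1 else None
        return blocks, anova

    blocks, anova = do_diversity()

    return PipelineResult(
        config=config,
        qc_report=qc_report,
        dataset=ds,
        roh_by_sample=roh_by_sample,
        froh=froh,
        levels=levels,
        cutoff=cutoff,
        islands=islands,
        cnvr_by_source=cnvr_by_source,
        excluded_samples=excluded_samples,
        fence_bp=fence_bp,
        fence_detail=fence_detail,
        gaps=gaps,
        audits=audits,
        coverage=coverage,
        permutations=permutations,
        blocks=blocks,
        anova=anova,
    )


def build_report(result: PipelineResult) -> dict:
    """JSON-serializable run report; deterministic for a fixed config + seed."""
    froh_values = np.array(list(result.froh.values()))
    report = {
        "config": result.config.to_dict(),
        "qc": result.qc_report.to_dict(orient="records"),
        "froh": {
            "per_sample": {k: float(v) for k, v in result.froh.items()},
            "mean": float(froh_values.mean()) if froh_values.size else 0.0,
        },
        "islands": {
            "cutoff_level": float(result.cutoff),
            "table": islands_table(result.islands).to_dict(orient="records"),
        },
        "cnvr": {
            tag: cnvr_summary(regions).to_dict(orient="records")
            for tag, regions in sorted(result.cnvr_by_source.items())
        },
        "excluded_samples": result.excluded_samples,
        "fence": {"fence_bp": float(result.fence_bp), "detail": result.fence_detail},
        "gaps": [
            {"chrom": g.chrom, "start": g.start, "end": g.end} for g in result.gaps
        ],
        "audit": {
            "table": audit_table(result.audits).to_dict(orient="records"),
            "coverage_summary": result.coverage.to_dict(orient="records"),
        },
        "permutation": {
            tag: res.as_mb_row(tag) for tag, res in sorted(result.permutations.items())
        },
        "diversity": {
            "blocks": result.blocks.to_dict(orient="records") if result.blocks is not None else [],
            "anova": result.anova.to_dict(orient="records") if result.anova is not None else [],
        },
    }
    return report


def write_artifacts(result: PipelineResult, outdir: str) -> dict[str, str]:
    """Write per-stage BED/TSV artifacts plus the JSON report."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    result.qc_report.to_csv(p("qc_report.tsv"), sep="\t", index=False)
    roh_rows, roh_names = [], []
    for sid, ivs in sorted(result.roh_by_sample.items()):
        for iv in ivs:
            roh_rows.append(iv)
            roh_names.append(sid)
    io.write_bed(roh_rows, p("roh_merged.bed"), names=roh_names, scores=[0] * len(roh_rows))
    mm = result.dataset.marker_map
    pd.DataFrame(
        {"chrom": mm.chrom, "pos": mm.pos_bp, "level": result.levels}
    ).to_csv(p("inbreeding_track.tsv"), sep="\t", index=False)
    io.write_bed(
        [i.interval for i in result.islands],
        p("islands.bed"),
        names=[f"island{k + 1}" for k in range(len(result.islands))],
        scores=[i.max_level for i in result.islands],
    )
    for tag, regions in sorted(result.cnvr_by_source.items()):
        io.write_bed(
            [r.interval for r in regions],
            p(f"cnvr_{tag}.bed"),
            names=[r.category for r in regions],
            scores=[r.n_samples for r in regions],
        )
        cnvr_summary(regions).to_csv(p(f"cnvr_{tag}_summary.tsv"), sep="\t", index=False)
    io.write_bed(list(result.gaps), p("coverage_gaps.bed"))
    audit_table(result.audits).to_csv(p("island_audit.tsv"), sep="\t", index=False)
    result.coverage.to_csv(p("island_coverage_summary.tsv"), sep="\t", index=False)
    if result.permutations:
        pd.DataFrame(
            [res.as_mb_row(tag) for tag, res in sorted(result.permutations.items())]
        ).to_csv(p("permutation_report.tsv"), sep="\t", index=False)
    if result.blocks is not None:
        result.blocks.to_csv(p("haplotype_blocks.tsv"), sep="\t", index=False)
    if result.anova is not None:
        result.anova.to_csv(p("diversity_anova.tsv"), sep="\t", index=False)
    with open(p("report.json"), "w") as fh:
        json.dump(build_report(result), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def run_audit(config: RunConfig) -> PipelineResult:
    """File-driven entry point: read inputs, run every stage, write artifacts."""
    for name in ("ped_path", "map_path", "cnv_calls_a"):
        path = getattr(config, name)
        if path is None or not os.path.exists(path):
            raise FileNotFoundError(f"config.{name}: missing input file {path!r}")
    if config.consensus and (config.cnv_calls_b is None or not os.path.exists(config.cnv_calls_b)):
        raise FileNotFoundError("consensus requested but cnv_calls_b is missing")

    dataset = io.read_plink_text(config.ped_path, config.map_path)
    calls_a = io.read_cnv_calls(config.cnv_calls_a, config.coords_one_based_inclusive)
    calls_b = (
        io.read_cnv_calls(config.cnv_calls_b, config.coords_one_based_inclusive)
        if config.cnv_calls_b
        else None
    )
    haps = None
    if config.haplotypes_path:
        mm, sample_ids, alleles = io.read_haplotypes(config.haplotypes_path)
        haps = PhasedHaplotypes(mm, sample_ids, alleles)
        # align the haplotype map to the post-QC marker set inside diversity
    result = run_pipeline(dataset, calls_a, calls_b, haps, config)
    write_artifacts(result, config.outdir)
    return result
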