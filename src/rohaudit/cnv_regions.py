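"""From per-sample CNV calls to CNV regions (CNVRs) and caller consensus.

Call cleaning merges same-sample, same-state neighbours separated by a
gap shorter than 20% of their combined length. Outlier samples are
excluded by Tukey's 1.5x-IQR rule on per-sample call counts. CNVRs are
single-linkage merges of calls overlapping by at least one base pair,
labelled gain/loss/both from the contributing states; consensus CNVRs
are base-pair intersections of two callers' CNVR sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import CnvCall, Cnvr, GenomicInterval, chrom_sort_key
from .roh_detection import BOVINE_AUTOSOME_BP


def discretize_segment(segment_mean: float, threshold: float = 0.3) -> int:
    """Three-state discretization of a segment mean: -1 loss, 0 neutral, +1 gain.

    The boundary is inclusive: ``|mean| >= threshold`` is called.
    """
    if not np.isfinite(segment_mean):
        raise ValueError("segment mean must be finite")
    if segment_mean >= threshold:
        return 1
    if segment_mean <= -threshold:
        return -1
    return 0


def clean_calls(calls: list[CnvCall], gap_fraction: float = 0.2) -> list[CnvCall]:
    """Iteratively merge same-sample same-state neighbours with short gaps.

    Two consecutive calls are merged when the gap between them is shorter
    than ``gap_fraction`` times their combined length; merging repeats to a
    fixed point (a merged, longer call can absorb further neighbours).
    """
    groups: dict[tuple, list[CnvCall]] = {}
    for c in calls:
        key = (c.sample_id, c.caller, c.interval.chrom, c.state)
        groups.setdefault(key, []).append(c)

    out: list[CnvCall] = []
    for key, group in groups.items():
        group = sorted(group, key=lambda c: (c.interval.start, c.interval.end))
        changed = True
        while changed:
            changed = False
            merged: list[CnvCall] = []
            for c in group:
                if merged:
                    prev = merged[-1]
                    gap = c.interval.start - prev.interval.end
                    if gap < gap_fraction * (prev.interval.length + c.interval.length):
                        merged[-1] = CnvCall(
                            sample_id=prev.sample_id,
                            interval=GenomicInterval(
                                prev.interval.chrom,
                                prev.interval.start,
                                max(prev.interval.end, c.interval.end),
                            ),
                            state=prev.state,
                            caller=prev.caller,
                        )
                        changed = True
                        continue
                merged.append(c)
            group = merged
        out.extend(group)
    out.sort(key=lambda c: (*c.interval.sort_key(), c.sample_id, c.state))
    return out


def tukey_quartiles(values) -> tuple[float, float]:
    """Type-7 (linear interpolation) first and third quartiles."""
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    return float(q1), float(q3)


def filter_samples_by_call_count(
    calls: list[CnvCall],
) -> tuple[list[CnvCall], list[str], float]:
    """Exclude samples whose call count exceeds the Tukey upper fence.

    Returns (kept calls, excluded sample ids, fence). With fewer than 4
    samples the fence is undefined and the input passes through unchanged.
    """
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    if len(counts) < 4:
        warnings.warn("fewer than 4 samples: call-count fence undefined, no exclusion")
        return list(calls), [], float("nan")
    q1, q3 = tukey_quartiles(list(counts.values()))
    fence = q3 + 1.5 * (q3 - q1)
    excluded = sorted(s for s, n in counts.items() if n > fence)
    kept = [c for c in calls if c.sample_id not in set(excluded)]
    return kept, excluded, fence


def build_cnvr(calls: list[CnvCall], caller: str = "") -> list[Cnvr]:
    """Single-linkage merge of calls overlapping by >= 1 bp into CNVRs.

    Book-ended calls (gap 0, no shared base) are not merged. The category
    is gain/loss when only one state contributed, both otherwise; the
    support count is the number of distinct contributing samples.
    """
    if not calls:
        return []
    tag = caller or calls[0].caller
    calls = sorted(calls, key=lambda c: c.interval.sort_key())
    regions: list[Cnvr] = []
    cur = calls[0]
    chrom, start, end = cur.interval.chrom, cur.interval.start, cur.interval.end
    states = {cur.state}
    samples = {cur.sample_id}
    for c in calls[1:]:
        if c.interval.chrom == chrom and c.interval.start < end:
            end = max(end, c.interval.end)
            states.add(c.state)
            samples.add(c.sample_id)
        else:
            regions.append(_make_cnvr(chrom, start, end, states, samples, tag))
            chrom, start, end = c.interval.chrom, c.interval.start, c.interval.end
            states = {c.state}
            samples = {c.sample_id}
    regions.append(_make_cnvr(chrom, start, end, states, samples, tag))
    return regions


def _make_cnvr(chrom, start, end, states, samples, caller) -> Cnvr:
    if states == {1}:
        category = "gain"
    elif states == {-1}:
        category = "loss"
    else:
        category = "both"
    return Cnvr(GenomicInterval(chrom, start, end), category, len(samples), caller)


def consensus_cnvr(cnvr_a: list[Cnvr], cnvr_b: list[Cnvr]) -> list[Cnvr]:
    """Base-pair intersections of two CNVR sets.

    Each output region is the overlap of one region from each input; the
    category is the shared one when the parents agree and neither is
    "both", otherwise "both". Support is the smaller parent support.
    """
    out: list[Cnvr] = []
    for ra in cnvr_a:
        for rb in cnvr_b:
            inter = ra.interval.intersection(rb.interval)
            if inter is None:
                continue
            if ra.category == rb.category and ra.category != "both":
                category = ra.category
            else:
                category = "both"
            out.append(Cnvr(inter, category, min(ra.n_samples, rb.n_samples), "consensus"))
    out.sort(key=lambda r: r.interval.sort_key())
    return out


def cnvr_summary(
    cnvrs: list[Cnvr], genome_length_bp: int = BOVINE_AUTOSOME_BP
) -> pd.DataFrame:
    """Per-category CNVR counts, length statistics and genome coverage."""
    rows = []
    by_cat: dict[str, list[Cnvr]] = {}
    for r in cnvrs:
        by_cat.setdefault(r.category, []).append(r)
    for cat in ("loss", "gain", "both"):
        group = by_cat.get(cat)
        if not group:
            continue
        lengths = np.array([r.interval.length for r in group], dtype=float)
        rows.append(
            {
                "category": cat,
                "n": len(group),
                "mean_length_bp": float(lengths.mean()),
                "median_length_bp": float(np.median(lengths)),
                "min_length_bp": float(lengths.min()),
                "max_length_bp": float(lengths.max()),
                "coverage_mb": float(lengths.sum()) / 1e6,
                "coverage_pct": 100.0 * float(lengths.sum()) / genome_length_bp,
            }
        )
    if cnvrs:
        lengths = np.array([r.interval.length for r in cnvrs], dtype=float)
        rows.append(
            {
                "category": "overall",
                "n": len(cnvrs),
                "mean_length_bp": float(lengths.mean()),
                "median_length_bp": float(np.median(lengths)),
                "min_length_bp": float(lengths.min()),
                "max_length_bp": float(lengths.max()),
                "coverage_mb": float(lengths.sum()) / 1e6,
                "coverage_pct": 100.0 * float(lengths.sum()) / genome_length_bp,
            }
        )
    return pd.DataFrame(rows)


def cnvr_set(cnvrs: list[Cnvr], categories: tuple[str, ...] = ("loss", "gain", "both")):
    """IntervalSet of CNVRs restricted to the given categories."""
    from .core import IntervalSet

    return IntervalSet(r.interval for r in cnvrs if r.category in categories)
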