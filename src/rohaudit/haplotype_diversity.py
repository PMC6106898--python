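"""Haplotype diversity inside ROH islands.

Each island is tiled into 100-kb blocks. Within a block, every phased
chromosome copy contributes one haplotype (its allele string over the
block's markers); the effective number of haplotypes is 1 / sum(p^2)
and the expected block heterozygosity H = 1 - sum(p^2), where p are the
haplotype frequencies. Diversity is compared across island categories
(and breeds, when more than one) by a two-way fixed-effects ANOVA
without interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DataError, GenomicInterval, MarkerMap
from .io_formats import HAP_MISSING


@dataclass
class PhasedHaplotypes:
    """Phased alleles (2N, n_markers) aligned with a marker map.

    Rows 2j and 2j+1 are the two chromosome copies of sample j. Allele
    codes are small non-negative integers; -9 marks a missing allele.
    """

    marker_map: MarkerMap
    sample_ids: list[str]
    alleles: np.ndarray

    def __post_init__(self):
        if self.alleles.shape != (2 * len(self.sample_ids), len(self.marker_map)):
            raise DataError("alleles must be shaped (2*n_samples, n_markers)")


def make_blocks(
    island: GenomicInterval,
    marker_map: MarkerMap,
    block_size: int = 100_000,
    min_markers: int = 2,
) -> list[GenomicInterval]:
    """Consecutive non-overlapping tiles of ``block_size`` from the island start.

    The trailing partial tile is kept, like any tile, only if it contains at
    least ``min_markers`` markers.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    blocks = []
    for start in range(island.start, island.end, block_size):
        tile = GenomicInterval(island.chrom, start, min(start + block_size, island.end))
        lo, hi = marker_map.markers_in(tile)
        if hi - lo >= min_markers:
            blocks.append(tile)
    return blocks


def haplotype_frequencies(haps: PhasedHaplotypes, block: GenomicInterval) -> np.ndarray:
    """Haplotype frequency vector for a block, in descending order.

    Chromosome copies with any missing allele in the block are excluded
    from the denominator.
    """
    mm = haps.marker_map
    sl = mm.chrom_slice(block.chrom)
    lo, hi = mm.markers_in(block)
    sub = haps.alleles[:, sl.start + lo : sl.start + hi]
    if sub.shape[1] == 0:
        raise DataError(f"block {block.chrom}:{block.start}-{block.end} has no markers")
    complete = ~np.any(sub == HAP_MISSING, axis=1)
    sub = sub[complete]
    if sub.shape[0] == 0:
        raise DataError("no chromosome copy has complete alleles in the block")
    _, counts = np.unique(sub, axis=0, return_counts=True)
    p = np.sort(counts / counts.sum())[::-1]
    return p


def block_stats(p: np.ndarray) -> tuple[float, float]:
    """(effective_n, H) from a haplotype frequency vector."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {p.sum()!r}")
    sum_sq = float(np.sum(p**2))
    return 1.0 / sum_sq, 1.0 - sum_sq


def block_table(
    islands_with_labels: Sequence[tuple[GenomicInterval, str]],
    haps: PhasedHaplotypes,
    block_size: int = 100_000,
    min_markers: int = 2,
    breed: str = "breed1",
) -> pd.DataFrame:
    """Per-block diversity table across labelled islands."""
    rows = []
    for island, label in islands_with_labels:
        for block in make_blocks(island, haps.marker_map, block_size, min_markers):
            p = haplotype_frequencies(haps, block)
            eff_n, h = block_stats(p)
            lo, hi = haps.marker_map.markers_in(block)
            rows.append(
                {
                    "island": f"{island.chrom}:{island.start}-{island.end}",
                    "chrom": block.chrom,
                    "block_start": block.start,
                    "block_end": block.end,
                    "n_markers": hi - lo,
                    "n_haplotypes": int(p.size),
                    "effective_n": eff_n,
                    "H": h,
                    "category": label,
                    "breed": breed,
                }
            )
    return pd.DataFrame(rows)


def compare_categories(
    blocks: pd.DataFrame,
    responses: Sequence[str] = ("n_haplotypes", "n_markers", "effective_n", "H"),
    factors: Sequence[str] = ("breed", "category"),
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (no interaction) per response variable.

    Factors with a single level are dropped (recorded in the output); a
    response with zero variance yields p = 1 for every factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    usable = [f for f in factors if blocks[f].nunique() > 1]
    dropped = [f for f in factors if f not in usable]
    rows = []
    for resp in responses:
        y = blocks[resp].to_numpy(dtype=float)
        if not usable or np.allclose(y, y[0]):
            for f in usable or list(factors):
                rows.append({"response": resp, "factor": f, "F": 0.0, "pvalue": 1.0})
            continue
        formula = f"Q('{resp}') ~ " + " + ".join(f"C({f})" for f in usable)
        model = smf.ols(formula, data=blocks).fit()
        table = sm.stats.anova_lm(model, typ=2)
        for f in usable:
            row = table.loc[f"C({f})"]
            fstat = float(row["F"])
            pval = float(row["PR(>F)"])
            if not np.isfinite(fstat):
                fstat, pval = 0.0, 1.0
            rows.append({"response": resp, "factor": f, "F": fstat, "pvalue": pval})
    out = pd.DataFrame(rows)
    out.attrs["dropped_factors"] = dropped
    return out


def compare_categories_rank(
    blocks: pd.DataFrame,
    responses: Sequence[str] = ("n_haplotypes", "n_markers", "effective_n", "H"),
    factor: str = "category",
) -> pd.DataFrame:
    """Kruskal-Wallis alternative for a single factor (rank-based)."""
    from scipy import stats

    rows = []
    for resp in responses:
        groups = [g[resp].to_numpy(dtype=float) for _, g in blocks.groupby(factor)]
        if len(groups) < 2 or all(np.allclose(g, groups[0][0]) for g in groups):
            rows.append({"response": resp, "factor": factor, "H_stat": 0.0, "pvalue": 1.0})
            continue
        stat, p = stats.kruskal(*groups)
        rows.append({"response": resp, "factor": factor, "H_stat": float(stat), "pvalue": float(p)})
    return pd.DataFrame(rows)
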