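"""Per-individual detection of runs of homozygosity (ROH).

ROH are called per length class with class-specific allowances for
heterozygous and missing genotypes (defaults: classes 1-2, 2-4, 4-8,
8-16 and >16 Mb allowing 1, 2, 4, 8, 16 heterozygotes and 4, 8, 16, 32,
64 missing calls respectively). Within a class the detector returns all
*maximal* marker windows: windows that satisfy the allowances and cannot
be extended by one marker in either direction without violating them,
trimmed so that both end markers are homozygous non-missing calls, and
whose base-pair span (last - first marker position + 1, on the 1-based
map) falls inside the class length bounds. Class-level calls are merged
per individual into a disjoint interval set, from which F_ROH is the
covered fraction of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import (
    DataError,
    GenomicInterval,
    GenotypeDataset,
    IntervalSet,
    MISSING,
    merge_intervals,
)

#: Bovine autosomal genome size used as the default F_ROH denominator.
BOVINE_AUTOSOME_BP = 2_511_000_000


@dataclass(frozen=True)
class RohClassParams:
    """Allowances for one ROH length class; ``max_length_bp=None`` = open-ended."""

    min_length_bp: int
    max_length_bp: Optional[int]
    max_het: int
    max_missing: int

    def __post_init__(self):
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        if self.max_length_bp is not None and self.max_length_bp <= self.min_length_bp:
            raise ValueError("max_length_bp must exceed min_length_bp")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("allowances must be non-negative")


DEFAULT_ROH_CLASSES: tuple[RohClassParams, ...] = (
    RohClassParams(1_000_000, 2_000_000, 1, 4),
    RohClassParams(2_000_000, 4_000_000, 2, 8),
    RohClassParams(4_000_000, 8_000_000, 4, 16),
    RohClassParams(8_000_000, 16_000_000, 8, 32),
    RohClassParams(16_000_000, None, 16, 64),
)


@dataclass(frozen=True)
class RohSegment:
    sample_id: str
    interval: GenomicInterval
    n_markers: int
    n_het: int
    n_missing: int

    @property
    def span_bp(self) -> int:
        """1-based inclusive span between the flanking markers."""
        return self.interval.length


def detect_roh_class(
    genotypes: np.ndarray,
    positions: np.ndarray,
    params: RohClassParams,
    chrom: str = "1",
    sample_id: str = "",
) -> list[RohSegment]:
    """All maximal qualifying windows for one sample on one chromosome.

    ``genotypes`` is a 1-D array of codes {0,1,2,-9} aligned with the sorted
    1-based ``positions``. Fewer than 2 markers yields an empty result.
    """
    g = np.asarray(genotypes)
    pos = np.asarray(positions, dtype=np.int64)
    n = len(g)
    if n < 2:
        return []

    het = (g == 1).astype(np.int64)
    miss = (g == MISSING).astype(np.int64)
    hom = (g != 1) & (g != MISSING)
    cum_het = np.concatenate(([0], np.cumsum(het)))
    cum_miss = np.concatenate(([0], np.cumsum(miss)))

    # right boundary R[i]: largest j with window [i..j] inside the allowances
    k_het = np.searchsorted(cum_het, cum_het[:-1] + params.max_het, side="right")
    k_miss = np.searchsorted(cum_miss, cum_miss[:-1] + params.max_missing, side="right")
    right = np.minimum(k_het, k_miss) - 2
    right = np.minimum(right, n - 1)

    # nearest homozygous marker on each side (for trimming)
    idx = np.arange(n)
    prev_hom = np.where(hom, idx, -1)
    np.maximum.accumulate(prev_hom, out=prev_hom)
    next_hom = np.where(hom, idx, n)
    next_hom = np.minimum.accumulate(next_hom[::-1])[::-1]

    segments: list[RohSegment] = []
    seen: set[tuple[int, int]] = set()
    valid = right >= idx
    maximal = valid & np.concatenate(([True], right[:-1] < right[1:]))
    for i in np.nonzero(maximal)[0]:
        j = right[i]
        a = next_hom[i]
        b = prev_hom[j]
        if a > b or (a, b) in seen:
            continue
        span = int(pos[b] - pos[a]) + 1
        if span < params.min_length_bp:
            continue
        if params.max_length_bp is not None and span >= params.max_length_bp:
            continue
        seen.add((a, b))
        segments.append(
            RohSegment(
                sample_id=sample_id,
                interval=GenomicInterval(chrom, int(pos[a]) - 1, int(pos[b])),
                n_markers=int(b - a + 1),
                n_het=int(cum_het[b + 1] - cum_het[a]),
                n_missing=int(cum_miss[b + 1] - cum_miss[a]),
            )
        )
    return segments


def detect_roh(
    dataset: GenotypeDataset,
    classes: Sequence[RohClassParams] = DEFAULT_ROH_CLASSES,
) -> list[RohSegment]:
    """Run every length class for every sample and chromosome."""
    segments: list[RohSegment] = []
    mm = dataset.marker_map
    for chrom in mm.chromosomes():
        sl = mm.chrom_slice(chrom)
        pos = mm.positions(chrom)
        block = dataset.genotypes[sl]
        for j, sid in enumerate(dataset.sample_ids):
            col = block[:, j]
            for params in classes:
                segments.extend(detect_roh_class(col, pos, params, chrom, sid))
    return segments


def merge_roh(segments: Iterable[RohSegment]) -> dict[str, IntervalSet]:
    """Per-sample union of class-level segments (book-ended runs coalesced)."""
    by_sample: dict[str, list[GenomicInterval]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg.interval)
    return {
        sid: IntervalSet(merge_intervals(ivs)) for sid, ivs in sorted(by_sample.items())
    }


def f_roh(merged: IntervalSet, genome_length_bp: int = BOVINE_AUTOSOME_BP) -> float:
    """Genomic inbreeding coefficient: summed ROH length over genome length."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    if not merged.is_disjoint():
        raise DataError("f_roh requires a merged (disjoint) ROH set")
    return merged.total_length() / genome_length_bp
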