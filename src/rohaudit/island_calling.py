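"""ROH islands: per-marker inbreeding levels and 99th-percentile calling.

The per-marker inbreeding level is the proportion of individuals whose
merged ROH cover the marker. Islands are maximal runs of consecutive
markers whose level strictly exceeds the genome-wide percentile cutoff
(linear-interpolation / type-7 quantile), with runs shorter than
``min_markers`` discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, IntervalSet, MarkerMap


@dataclass(frozen=True)
class Island:
    interval: GenomicInterval
    n_markers: int
    max_level: float


def marker_inbreeding_levels(
    roh_by_sample: dict[str, IntervalSet], marker_map: MarkerMap
) -> np.ndarray:
    """Proportion of samples in ROH at each marker, aligned with the map.

    Each sample's set must already be merged (disjoint), so a sample counts
    at most once per marker.
    """
    n_samples = len(roh_by_sample)
    if n_samples == 0:
        raise ValueError("marker_inbreeding_levels requires at least one sample")
    counts = np.zeros(len(marker_map), dtype=np.int64)
    chroms = set(marker_map.chromosomes())
    for sid, ivset in roh_by_sample.items():
        if not ivset.is_disjoint():
            raise ValueError(f"sample {sid}: ROH set must be merged before computing levels")
        diff = np.zeros(len(marker_map) + 1, dtype=np.int64)
        for iv in ivset:
            if iv.chrom not in chroms:
                continue
            sl = marker_map.chrom_slice(iv.chrom)
            lo, hi = marker_map.markers_in(iv)
            diff[sl.start + lo] += 1
            diff[sl.start + hi] -= 1
        counts += np.cumsum(diff[:-1])
    return counts / n_samples


def island_threshold(levels: np.ndarray, percentile: float = 99.0) -> float:
    """Type-7 (linear interpolation) percentile of the level track."""
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("empty level track")
    return float(np.percentile(levels, percentile, method="linear"))


def call_islands(
    levels: np.ndarray,
    marker_map: MarkerMap,
    cutoff: float,
    min_markers: int = 2,
) -> list[Island]:
    """Maximal runs of markers with level strictly above the cutoff.

    The island interval spans the first to last marker of the run
    (half-open). Runs are never bridged across sub-threshold markers.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    levels = np.asarray(levels, dtype=float)
    islands: list[Island] = []
    for chrom in marker_map.chromosomes():
        sl = marker_map.chrom_slice(chrom)
        flagged = levels[sl] > cutoff
        if not flagged.any():
            continue
        padded = np.concatenate(([False], flagged, [False])).astype(np.int8)
        edges = np.diff(padded)
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]  # exclusive
        for a, b in zip(starts, ends):
            if b - a < min_markers:
                continue
            islands.append(
                Island(
                    interval=marker_map.marker_interval(chrom, a, b - 1),
                    n_markers=int(b - a),
                    max_level=float(levels[sl][a:b].max()),
                )
            )
    return islands


def islands_table(islands: list[Island]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": isl.interval.chrom,
                "start": isl.interval.start,
                "end": isl.interval.end,
                "length_bp": isl.interval.length,
                "n_markers": isl.n_markers,
                "max_level": isl.max_level,
            }
            for isl in islands
        ]
    )


def island_set(islands: list[Island]) -> IntervalSet:
    return IntervalSet(isl.interval for isl in islands)
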