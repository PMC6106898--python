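"""Intermarker distances, the Tukey outlier fence, and coverage gaps.

A coverage gap is the marker-free stretch between two consecutive
markers whose distance exceeds the Tukey upper fence (Q3 + 1.5xIQR of
the genome-wide intermarker-distance distribution, type-7 quartiles).
For runs on the real BovineHD chip map the published fence of 9.2365 kb
is available as a documented default constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DataError, GenomicInterval, IntervalSet, MarkerMap

#: Upper outlier fence (bp) for intermarker distances on the BovineHD chip map.
BOVINEHD_FENCE_BP = 9236.5


@dataclass(frozen=True)
class GapFence:
    q1: float
    q3: float
    fence: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def intermarker_distances(marker_map: MarkerMap) -> dict[str, np.ndarray]:
    """Distances between consecutive markers, per chromosome.

    Never spans chromosomes; a single-marker chromosome yields an empty
    array. Duplicate positions are a data error (also enforced by the map).
    """
    out: dict[str, np.ndarray] = {}
    for chrom in marker_map.chromosomes():
        d = np.diff(marker_map.positions(chrom))
        if np.any(d == 0):
            raise DataError(f"duplicate marker positions on chromosome {chrom}")
        out[chrom] = d
    return out


def all_distances(imd: dict[str, np.ndarray]) -> np.ndarray:
    arrays = [d for d in imd.values() if d.size]
    return np.concatenate(arrays) if arrays else np.array([], dtype=np.int64)


def tukey_upper_fence(values) -> GapFence:
    """Q3 + 1.5xIQR with type-7 (linear interpolation) quartiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("tukey_upper_fence requires at least 4 values")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    return GapFence(q1=float(q1), q3=float(q3), fence=float(q3 + 1.5 * (q3 - q1)))


def gap_intervals(marker_map: MarkerMap, fence_bp: float) -> IntervalSet:
    """Marker-free intervals between consecutive-marker pairs with distance > fence.

    For a pair at 1-based positions (p, q) the gap is the half-open interval
    [p, q-1): every base strictly between the two markers.
    """
    if fence_bp <= 0:
        raise ValueError("fence must be positive")
    gaps = []
    for chrom in marker_map.chromosomes():
        pos = marker_map.positions(chrom)
        d = np.diff(pos)
        for i in np.nonzero(d > fence_bp)[0]:
            gaps.append(GenomicInterval(chrom, int(pos[i]), int(pos[i + 1]) - 1))
    return IntervalSet(gaps)


def mean_island_imd(island: GenomicInterval, marker_map: MarkerMap) -> float:
    """Mean distance between consecutive markers inside an island.

    With fewer than 2 markers the mean is undefined; NaN is returned with a
    warning and the caller treats the island as failing the IMD check.
    """
    lo, hi = marker_map.markers_in(island)
    pos = marker_map.positions(island.chrom)[lo:hi]
    if len(pos) < 2:
        warnings.warn(
            f"island {island.chrom}:{island.start}-{island.end} has fewer than "
            "2 markers; mean IMD undefined"
        )
        return float("nan")
    return float(np.mean(np.diff(pos)))
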