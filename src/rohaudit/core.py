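"""Core domain types and interval algebra.

Coordinate contract
-------------------
Every interval in the package is 0-based half-open (BED convention).
Marker positions are kept as read from file, i.e. 1-based base-pair
positions; a marker at position ``p`` occupies the interval ``[p-1, p)``.
A 1-based inclusive region ``[s, e]`` converts to ``[s-1, e)``, which
preserves the conventional inclusive span ``e - s + 1`` as its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np


class DataError(ValueError):
    """Malformed or contract-violating input data."""


def chrom_sort_key(chrom: str):
    """Sort chromosomes numerically when possible, lexically otherwise."""
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def sort_key(self):
        return (*chrom_sort_key(self.chrom), self.start, self.end)


def merge_intervals(
    intervals: Iterable[GenomicInterval], coalesce_book_ended: bool = True
) -> list[GenomicInterval]:
    """Union of intervals: sorted, pairwise disjoint.

    Book-ended intervals (gap of exactly 0) are coalesced by default,
    matching ``bedtools merge`` semantics.
    """
    items = sorted(intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    for iv in items:
        if out and out[-1].chrom == iv.chrom:
            prev = out[-1]
            touching = iv.start <= prev.end if coalesce_book_ended else iv.start < prev.end
            if touching:
                if iv.end > prev.end:
                    out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
                continue
        out.append(iv)
    return out


class IntervalSet:
    """An immutable, sorted collection of intervals (possibly overlapping)."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=GenomicInterval.sort_key)
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet({list(self._intervals)!r})"

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return self._intervals

    def merged(self, coalesce_book_ended: bool = True) -> "IntervalSet":
        return IntervalSet(merge_intervals(self._intervals, coalesce_book_ended))

    def is_disjoint(self) -> bool:
        for a, b in zip(self._intervals, self._intervals[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                return False
        return True

    def total_length(self) -> int:
        return sum(iv.length for iv in self._intervals)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def on_chrom(self, chrom: str) -> "IntervalSet":
        return IntervalSet(iv for iv in self._intervals if iv.chrom == chrom)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays of this set's intervals on one chromosome."""
        ivs = [iv for iv in self._intervals if iv.chrom == chrom]
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        return starts, ends


def intersect_length(set_a: IntervalSet, set_b: IntervalSet) -> dict[str, int]:
    """Base pairs shared by two interval unions, per chromosome plus ``total``.

    Both inputs are merged internally, so overlapping members of one set
    are not double counted.
    """
    a = set_a.merged()
    b = set_b.merged()
    out: dict[str, int] = {}
    total = 0
    for chrom in a.chromosomes():
        sa, ea = a.arrays(chrom)
        sb, eb = b.arrays(chrom)
        if len(sb) == 0:
            continue
        bp = 0
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if lo < hi:
                bp += int(hi - lo)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
        if bp:
            out[chrom] = bp
            total += bp
    out["total"] = total
    return out


def intersection_set(set_a: IntervalSet, set_b: IntervalSet) -> IntervalSet:
    """Interval union intersection, as an IntervalSet."""
    a = set_a.merged()
    b = set_b.merged()
    out: list[GenomicInterval] = []
    for chrom in a.chromosomes():
        sa, ea = a.arrays(chrom)
        sb, eb = b.arrays(chrom)
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if lo < hi:
                out.append(GenomicInterval(chrom, int(lo), int(hi)))
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return IntervalSet(out)


MISSING = -9  # genotype code for a missing call


class MarkerMap:
    """Ordered marker positions per chromosome; the coordinate backbone.

    Parameters
    ----------
    chroms, marker_ids, positions
        Parallel sequences. Positions are 1-based base pairs as read from
        file. Markers are stored sorted by (chromosome, position) with the
        chromosome order given by :func:`chrom_sort_key`.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        marker_ids: Sequence[str],
        positions: Sequence[int],
    ):
        n = len(marker_ids)
        if not (len(chroms) == len(positions) == n):
            raise DataError("marker map fields must have equal length")
        order = sorted(
            range(n), key=lambda i: (*chrom_sort_key(str(chroms[i])), int(positions[i]))
        )
        self.chrom = np.array([str(chroms[i]) for i in order], dtype=object)
        self.marker_id = np.array([str(marker_ids[i]) for i in order], dtype=object)
        self.pos_bp = np.array([int(positions[i]) for i in order], dtype=np.int64)
        self._order = np.array(order, dtype=np.int64)
        if len(set(self.marker_id)) != n:
            raise DataError("duplicate marker ids in map")
        # per-chromosome slices, in sorted chromosome order
        self._slices: dict[str, slice] = {}
        start = 0
        for i in range(1, n + 1):
            if i == n or self.chrom[i] != self.chrom[start]:
                c = str(self.chrom[start])
                if c in self._slices:
                    raise DataError(f"chromosome {c} appears in disjoint blocks")
                self._slices[c] = slice(start, i)
                pos = self.pos_bp[start:i]
                if np.any(np.diff(pos) <= 0):
                    raise DataError(
                        f"marker positions not strictly increasing on chromosome {c}"
                    )
                start = i

    def __len__(self) -> int:
        return len(self.pos_bp)

    @property
    def input_order(self) -> np.ndarray:
        """Permutation applied to the constructor input (for aligning payloads)."""
        return self._order

    def chromosomes(self) -> list[str]:
        return list(self._slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[chrom]

    def positions(self, chrom: str) -> np.ndarray:
        return self.pos_bp[self._slices[chrom]]

    def chrom_span(self, chrom: str) -> int:
        """Position of the last marker on the chromosome (a usable length proxy)."""
        return int(self.positions(chrom)[-1])

    def marker_interval(self, chrom: str, first_idx: int, last_idx: int) -> GenomicInterval:
        """Half-open interval spanning markers ``first_idx..last_idx`` (chromosome-local)."""
        pos = self.positions(chrom)
        return GenomicInterval(chrom, int(pos[first_idx]) - 1, int(pos[last_idx]))

    def markers_in(self, interval: GenomicInterval) -> tuple[int, int]:
        """Chromosome-local index range [lo, hi) of markers inside an interval."""
        pos = self.positions(interval.chrom)
        lo = int(np.searchsorted(pos, interval.start + 1, side="left"))
        hi = int(np.searchsorted(pos, interval.end, side="right"))
        return lo, hi


class GenotypeDataset:
    """Marker-by-sample genotype codes bound to a :class:`MarkerMap`.

    Codes: 0 = homozygous for the lexically first allele, 1 = heterozygous,
    2 = homozygous for the second allele, -9 = missing.
    """

    VALID_CODES = frozenset({0, 1, 2, MISSING})

    def __init__(self, marker_map: MarkerMap, sample_ids: Sequence[str], genotypes: np.ndarray):
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(marker_map), len(sample_ids)):
            raise DataError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"({len(marker_map)} markers, {len(sample_ids)} samples)"
            )
        bad = set(np.unique(genotypes)) - self.VALID_CODES
        if bad:
            raise DataError(f"invalid genotype codes {sorted(bad)}")
        self.marker_map = marker_map
        self.sample_ids = [str(s) for s in sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids")
        self.genotypes = genotypes

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.genotypes[:, self.sample_ids.index(sample_id)]

    def subset(self, marker_mask: np.ndarray, sample_mask: np.ndarray) -> "GenotypeDataset":
        mm = MarkerMap(
            self.marker_map.chrom[marker_mask],
            self.marker_map.marker_id[marker_mask],
            self.marker_map.pos_bp[marker_mask],
        )
        samples = [s for s, keep in zip(self.sample_ids, sample_mask) if keep]
        return GenotypeDataset(mm, samples, self.genotypes[np.ix_(marker_mask, sample_mask)])


@dataclass
class IntensityTable:
    """Per-(marker, sample) B-allele frequency and log R ratio matrices."""

    marker_map: MarkerMap
    sample_ids: list[str]
    baf: np.ndarray  # (n_markers, n_samples) in [0, 1]
    lrr: np.ndarray  # (n_markers, n_samples)

    def __post_init__(self):
        shape = (len(self.marker_map), len(self.sample_ids))
        if self.baf.shape != shape or self.lrr.shape != shape:
            raise DataError("intensity matrices must be (n_markers, n_samples)")
        if np.any((self.baf < 0) | (self.baf > 1)):
            raise DataError("BAF values must lie in [0, 1]")


@dataclass(frozen=True)
class CnvCall:
    """One per-sample copy-state call: -1 = loss, +1 = gain."""

    sample_id: str
    interval: GenomicInterval
    state: int
    caller: str
    segment_mean: Optional[float] = None

    def __post_init__(self):
        if self.state not in (-1, 1):
            raise DataError(f"CNV call state must be -1 or +1, got {self.state}")


@dataclass(frozen=True)
class Cnvr:
    """A CNV region: merged overlapping calls with a gain/loss/both category."""

    interval: GenomicInterval
    category: str
    n_samples: int
    caller: str

    CATEGORIES = ("gain", "loss", "both")

    def __post_init__(self):
        if self.category not in self.CATEGORIES:
            raise DataError(f"unknown CNVR category {self.category!r}")
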