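"""Classify ROH islands against CNVRs and coverage gaps; permutation test.

An island is flagged ``gap`` when it overlaps a coverage-gap interval or
its mean intermarker distance exceeds the fence, ``loss``/``gain`` when
it overlaps a CNVR carrying that state. Islands flagged gap or loss are
verdicted as likely artefacts: deletions mistyped as homozygous and
marker-free stretches both manufacture spurious homozygosity, whereas a
copy gain does not (configurable). The permutation test re-places each
chromosome's islands uniformly at random (preserving count, lengths and
chromosome assignment, same-chromosome spacing > 1 Mb) and compares the
observed island x CNVR intersection (ROHD) with its randomized
distribution (ROHR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, IntervalSet, MarkerMap, intersect_length
from .cnv_regions import Cnvr, cnvr_set
from .coverage_gaps import mean_island_imd
from .island_calling import Island

LABEL_ORDER = ("gap", "loss", "gain")


@dataclass(frozen=True)
class IslandAudit:
    island: GenomicInterval
    mean_imd: float
    has_gap: bool
    has_loss: bool
    has_gain: bool
    overlap_bp: dict[str, int] = field(compare=False)
    gain_as_artefact: bool = False

    @property
    def label(self) -> str:
        parts = [
            name
            for name, flag in zip(LABEL_ORDER, (self.has_gap, self.has_loss, self.has_gain))
            if flag
        ]
        return "+".join(parts) if parts else "clean"

    @property
    def is_artefact(self) -> bool:
        verdict = self.has_gap or self.has_loss
        if self.gain_as_artefact:
            verdict = verdict or self.has_gain
        return verdict


def classify_island(
    island: GenomicInterval,
    cnvrs: Sequence[Cnvr],
    gaps: IntervalSet,
    fence_bp: float,
    marker_map: MarkerMap,
    gain_as_artefact: bool = False,
) -> IslandAudit:
    """Audit one island for gap/loss/gain interference."""
    isl_set = IntervalSet([island])
    overlap_bp = {
        cat: intersect_length(isl_set, cnvr_set(cnvrs, (cat,)))["total"]
        for cat in ("loss", "gain", "both")
    }
    gap_overlap = intersect_length(isl_set, gaps)["total"]
    mean_imd = mean_island_imd(island, marker_map)
    imd_fail = (not np.isfinite(mean_imd)) or mean_imd > fence_bp
    return IslandAudit(
        island=island,
        mean_imd=mean_imd,
        has_gap=gap_overlap > 0 or imd_fail,
        has_loss=overlap_bp["loss"] > 0 or overlap_bp["both"] > 0,
        has_gain=overlap_bp["gain"] > 0 or overlap_bp["both"] > 0,
        overlap_bp=overlap_bp,
        gain_as_artefact=gain_as_artefact,
    )


def audit_islands(
    islands: Sequence[Island],
    cnvrs: Sequence[Cnvr],
    gaps: IntervalSet,
    fence_bp: float,
    marker_map: MarkerMap,
    gain_as_artefact: bool = False,
) -> list[IslandAudit]:
    return [
        classify_island(isl.interval, cnvrs, gaps, fence_bp, marker_map, gain_as_artefact)
        for isl in islands
    ]


def coverage_summary(audits: Sequence[IslandAudit]) -> pd.DataFrame:
    """Numbers, lengths (Mb) and coverage percentages of islands per label.

    Percentages are of the total island coverage; the ``overall affected``
    row aggregates every non-clean island.
    """
    total_bp = sum(a.island.length for a in audits)
    by_label: dict[str, list[IslandAudit]] = {}
    for a in audits:
        by_label.setdefault(a.label, []).append(a)
    rows = []
    for label in sorted(by_label):
        group = by_label[label]
        bp = sum(a.island.length for a in group)
        rows.append(
            {
                "label": label,
                "n_islands": len(group),
                "coverage_mb": bp / 1e6,
                "pct_of_island_coverage": 100.0 * bp / total_bp if total_bp else 0.0,
            }
        )
    affected = [a for a in audits if a.label != "clean"]
    bp = sum(a.island.length for a in affected)
    rows.append(
        {
            "label": "overall affected",
            "n_islands": len(affected),
            "coverage_mb": bp / 1e6,
            "pct_of_island_coverage": 100.0 * bp / total_bp if total_bp else 0.0,
        }
    )
    return pd.DataFrame(rows)


def audit_table(audits: Sequence[IslandAudit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": a.island.chrom,
                "start": a.island.start,
                "end": a.island.end,
                "length_bp": a.island.length,
                "mean_imd_bp": a.mean_imd,
                "has_gap": a.has_gap,
                "has_loss": a.has_loss,
                "has_gain": a.has_gain,
                "label": a.label,
                "artefact": a.is_artefact,
                "overlap_loss_bp": a.overlap_bp["loss"],
                "overlap_gain_bp": a.overlap_bp["gain"],
                "overlap_both_bp": a.overlap_bp["both"],
            }
            for a in audits
        ]
    )


@dataclass(frozen=True)
class PermutationResult:
    rohd_bp: int
    rohr_mean_bp: float
    ci_low_bp: float
    ci_high_bp: float
    t_pvalue: float
    empirical_pvalue: float
    n_perm: int
    seed: Optional[int]

    def as_mb_row(self, source: str = "") -> dict:
        """Table row in Mb, mirroring the ROHD / ROHR report layout."""
        return {
            "source": source,
            "rohd_mb": self.rohd_bp / 1e6,
            "rohr_mean_mb": self.rohr_mean_bp / 1e6,
            "ci_low_mb": self.ci_low_bp / 1e6,
            "ci_high_mb": self.ci_high_bp / 1e6,
            "t_pvalue": self.t_pvalue,
            "empirical_pvalue": self.empirical_pvalue,
            "n_perm": self.n_perm,
        }


class PlacementError(RuntimeError):
    """Islands plus spacing do not fit (or rejection budget exceeded)."""


def _coverage_functions(cnvr: IntervalSet):
    """Per-chromosome cumulative-coverage interpolators for a merged set."""
    merged = cnvr.merged()
    fns = {}
    for chrom in merged.chromosomes():
        starts, ends = merged.arrays(chrom)
        cum = np.concatenate(([0], np.cumsum(ends - starts)))

        def cov(x, starts=starts, ends=ends, cum=cum):
            x = np.asarray(x, dtype=np.int64)
            i = np.searchsorted(starts, x, side="right") - 1
            i_clip = np.clip(i, 0, len(starts) - 1)
            inside = np.clip(x - starts[i_clip], 0, ends[i_clip] - starts[i_clip])
            return np.where(i < 0, 0, cum[i_clip] + inside)

        fns[chrom] = cov
    return fns


def _place_islands(
    lengths: np.ndarray,
    chrom_len: int,
    n_perm: int,
    min_gap_bp: int,
    rng: np.random.Generator,
    chrom: str,
    max_tries: int = 10_000,
) -> np.ndarray:
    """(n_perm, k) random starts with all pairwise gaps > min_gap_bp."""
    k = len(lengths)
    if lengths.sum() + (k - 1) * (min_gap_bp + 1) > chrom_len:
        raise PlacementError(
            f"chromosome {chrom}: {k} islands cannot be spaced > {min_gap_bp} bp apart"
        )
    starts = np.empty((n_perm, k), dtype=np.int64)
    pending = np.arange(n_perm)
    tries = 0
    while pending.size:
        draw = rng.integers(0, chrom_len - lengths + 1, size=(pending.size, k))
        if k == 1:
            starts[pending] = draw
            break
        order = np.argsort(draw, axis=1)
        s_sorted = np.take_along_axis(draw, order, axis=1)
        l_sorted = lengths[order]
        gaps = s_sorted[:, 1:] - (s_sorted[:, :-1] + l_sorted[:, :-1])
        ok = np.all(gaps > min_gap_bp, axis=1)
        starts[pending[ok]] = draw[ok]
        pending = pending[~ok]
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"chromosome {chrom}: rejection budget exceeded while spacing islands"
            )
    return starts


def permutation_test(
    islands: IntervalSet,
    cnvr: IntervalSet,
    chrom_lengths: dict[str, int],
    n_perm: int = 10_000,
    min_gap_bp: int = 1_000_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """Constrained-randomization test of island x CNVR overlap.

    Per replicate, each chromosome's islands are independently re-placed
    uniformly (count, lengths and chromosome assignment preserved) subject
    to same-chromosome gaps > ``min_gap_bp``; the statistic is the total
    base-pair intersection with the CNVR set. Reports the observed ROHD,
    the ROHR mean with a t-based 95% CI, a one-sample t-test of
    H0: mean(ROHR) = ROHD, and the empirical p-value
    (1 + #{ROHR >= ROHD}) / (1 + n_perm).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rohd = intersect_length(islands, cnvr)["total"]
    cov_fns = _coverage_functions(cnvr)
    rohr = np.zeros(n_perm, dtype=np.int64)
    for chrom in islands.merged().chromosomes():
        starts_obs, ends_obs = islands.merged().arrays(chrom)
        lengths = ends_obs - starts_obs
        if chrom not in chrom_lengths:
            raise ValueError(f"no length given for chromosome {chrom}")
        L = int(chrom_lengths[chrom])
        starts = _place_islands(lengths, L, n_perm, min_gap_bp, rng, chrom)
        cov = cov_fns.get(chrom)
        if cov is None:
            continue
        for j in range(len(lengths)):
            rohr += cov(starts[:, j] + lengths[j]) - cov(starts[:, j])

    mean = float(rohr.mean())
    if n_perm > 1 and rohr.std(ddof=1) > 0:
        sem = rohr.std(ddof=1) / np.sqrt(n_perm)
        tcrit = stats.t.ppf(0.975, df=n_perm - 1)
        ci = (mean - tcrit * sem, mean + tcrit * sem)
        t_p = float(stats.ttest_1samp(rohr, popmean=rohd).pvalue)
    else:
        ci = (mean, mean)
        t_p = 1.0 if mean == rohd else 0.0
    emp_p = (1 + int(np.sum(rohr >= rohd))) / (1 + n_perm)
    return PermutationResult(
        rohd_bp=int(rohd),
        rohr_mean_bp=mean,
        ci_low_bp=float(ci[0]),
        ci_high_bp=float(ci[1]),
        t_pvalue=t_p,
        empirical_pvalue=float(emp_p),
        n_perm=n_perm,
        seed=seed,
    )
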