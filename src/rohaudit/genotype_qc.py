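"""Marker and sample quality control preceding ROH analysis.

Filters, in fixed order: (1) samples by missing fraction / call rate,
(2) markers by missing fraction, (3) markers by a 1-df chi-square test of
Hardy-Weinberg equilibrium. The entity attribution of the thresholds
(marker vs sample) follows PLINK convention (mind before geno); the report
header records this reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, GenotypeDataset, MISSING


@dataclass(frozen=True)
class QcThresholds:
    max_marker_missing: float = 0.05
    max_sample_missing: float = 0.10
    min_sample_call_rate: float = 0.90
    hwe_alpha: float = 0.001

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def hwe_pvalue(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """1-df chi-square p-value for departure from Hardy-Weinberg proportions.

    The expectation uses the sample allele frequency. A monomorphic marker
    returns p = 1 (no testable departure). All-missing input is undefined.
    """
    counts = np.array([n_hom_a, n_het, n_hom_b], dtype=float)
    if np.any(counts < 0) or not np.all(counts == np.floor(counts)):
        raise ValueError("genotype counts must be non-negative integers")
    n = counts.sum()
    if n == 0:
        raise ValueError("all-missing marker: HWE p-value undefined")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues_vectorized(n_hom_a: np.ndarray, n_het: np.ndarray, n_hom_b: np.ndarray) -> np.ndarray:
    n = (n_hom_a + n_het + n_hom_b).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_hom_a + n_het) / (2 * n)
        q = 1.0 - p
        ea = n * p * p
        eh = 2 * n * p * q
        eb = n * q * q
        chi2 = (n_hom_a - ea) ** 2 / ea + (n_het - eh) ** 2 / eh + (n_hom_b - eb) ** 2 / eb
    pvals = stats.chi2.sf(chi2, df=1)
    pvals = np.where((p == 0) | (q == 0), 1.0, pvals)
    return np.where(n == 0, np.nan, pvals)


def apply_qc(
    dataset: GenotypeDataset, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Apply the sample-then-marker filters; return (filtered dataset, report).

    The report has one row per step with entity, counts before/after and the
    threshold applied. Raises :class:`DataError` if nothing survives.
    """
    g = dataset.genotypes
    report_rows = []

    # step 1: samples by missing fraction / call rate
    sample_missing = np.mean(g == MISSING, axis=0)
    keep_samples = (sample_missing <= thresholds.max_sample_missing) & (
        1.0 - sample_missing >= thresholds.min_sample_call_rate
    )
    report_rows.append(
        {
            "step": "sample_missingness",
            "entity": "sample",
            "threshold": f"missing<={thresholds.max_sample_missing};call_rate>={thresholds.min_sample_call_rate}",
            "count_before": dataset.n_samples,
            "count_after": int(keep_samples.sum()),
        }
    )
    g1 = g[:, keep_samples]

    # step 2: markers by missing fraction
    marker_missing = np.mean(g1 == MISSING, axis=1) if g1.shape[1] else np.ones(g1.shape[0])
    keep_missing = marker_missing <= thresholds.max_marker_missing
    report_rows.append(
        {
            "step": "marker_missingness",
            "entity": "marker",
            "threshold": f"missing<={thresholds.max_marker_missing}",
            "count_before": dataset.n_markers,
            "count_after": int(keep_missing.sum()),
        }
    )

    # step 3: markers by HWE (evaluated on surviving samples/markers)
    n_hom_a = np.sum(g1 == 0, axis=1).astype(float)
    n_het = np.sum(g1 == 1, axis=1).astype(float)
    n_hom_b = np.sum(g1 == 2, axis=1).astype(float)
    pvals = _hwe_pvalues_vectorized(n_hom_a, n_het, n_hom_b)
    keep_hwe = np.where(np.isnan(pvals), False, pvals >= thresholds.hwe_alpha)
    keep_markers = keep_missing & keep_hwe
    report_rows.append(
        {
            "step": "marker_hwe",
            "entity": "marker",
            "threshold": f"p>={thresholds.hwe_alpha}",
            "count_before": int(keep_missing.sum()),
            "count_after": int(keep_markers.sum()),
        }
    )

    if not keep_markers.any() or not keep_samples.any():
        raise DataError("QC removed all markers or all samples")
    filtered = dataset.subset(keep_markers, keep_samples)
    report = pd.DataFrame(report_rows)
    report.attrs["entity_reading"] = (
        "call-rate/missing-data thresholds read as sample filters, "
        "missing-genotype threshold as a marker filter (PLINK mind-then-geno order)"
    )
    return filtered, report
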