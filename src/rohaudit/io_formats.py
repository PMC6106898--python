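"""Readers and writers for the text formats the pipeline touches.

PLINK .ped/.map, BED3/BED5, CNV-call TSV, intensity (final-report-like)
TSV and phased-haplotype TSV. All coordinates are converted to the
internal 0-based half-open convention at this boundary and nowhere else;
PLINK map positions and CNV-call coordinates are declared 1-based
(inclusive for intervals) on disk.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CnvCall,
    DataError,
    GenomicInterval,
    GenotypeDataset,
    IntensityTable,
    IntervalSet,
    MarkerMap,
    MISSING,
)


class ParseError(ValueError):
    """Structurally malformed input file."""


# ---------------------------------------------------------------------------
# PLINK text


def read_plink_text(ped_path: os.PathLike | str, map_path: os.PathLike | str) -> GenotypeDataset:
    """Read a PLINK text fileset into a :class:`GenotypeDataset`.

    Alleles are mapped per marker by lexical order of the observed alleles:
    homozygous for the first allele -> 0, heterozygous -> 1, homozygous for
    the second -> 2; any "0" allele -> missing (-9). More than two distinct
    alleles at a marker is a data error.
    """
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{map_path}: line {ln}: expected 4 columns, got {len(fields)}")
            rows.append((fields[0], fields[1], int(fields[3])))
    marker_map = MarkerMap(
        [r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows]
    )
    n_markers = len(marker_map)

    sample_ids: list[str] = []
    columns: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_markers:
                raise ParseError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_markers} fields "
                    f"for {n_markers} markers, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            columns.append(np.array(fields[6:], dtype=object).reshape(n_markers, 2))
    if not sample_ids:
        raise ParseError(f"{ped_path}: no samples")

    # alleles in .ped follow .map file order; realign to the sorted map
    alleles = np.stack(columns, axis=1)  # (n_markers_file_order, n_samples, 2)
    alleles = alleles[marker_map.input_order]

    genotypes = np.full((n_markers, len(sample_ids)), MISSING, dtype=np.int8)
    for m in range(n_markers):
        a = alleles[m]
        missing = (a[:, 0] == "0") | (a[:, 1] == "0")
        observed = sorted(set(a[~missing].ravel()))
        if len(observed) > 2:
            raise DataError(
                f"marker {marker_map.marker_id[m]}: more than 2 alleles {observed}"
            )
        if not observed:
            continue
        first = observed[0]
        het = a[:, 0] != a[:, 1]
        hom_first = (~het) & (a[:, 0] == first)
        genotypes[m, ~missing & het] = 1
        genotypes[m, ~missing & hom_first] = 0
        genotypes[m, ~missing & ~het & ~hom_first] = 2
    return GenotypeDataset(marker_map, sample_ids, genotypes)


def write_plink_text(
    dataset: GenotypeDataset, ped_path: os.PathLike | str, map_path: os.PathLike | str
) -> None:
    """Write a dataset as PLINK text, using alleles A/B (missing -> "0 0")."""
    mm = dataset.marker_map
    with open(map_path, "w") as fh:
        for c, mid, p in zip(mm.chrom, mm.marker_id, mm.pos_bp):
            fh.write(f"{c}\t{mid}\t0\t{p}\n")
    allele_strings = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for j, sid in enumerate(dataset.sample_ids):
            col = dataset.genotypes[:, j]
            geno = " ".join(allele_strings[int(g)] for g in col)
            fh.write(f"FAM {sid} 0 0 0 -9 {geno}\n")


# ---------------------------------------------------------------------------
# CNV call tables

_STATE_TOKENS = {"-1": -1, "1": 1, "0": -1, "3": 1, "4": 1}
# copy numbers 0 and 1 are losses; 3 and 4 are gains


def _state_from_token(token: str) -> int:
    token = token.strip()
    if token not in _STATE_TOKENS:
        raise DataError(f"unknown CNV state token {token!r}")
    if token == "1":
        # "1" is ambiguous between state +1 and copy number 1; the table's
        # state column is declared to use the signed convention, so 1 = gain.
        return 1
    return _STATE_TOKENS[token]


def read_cnv_calls(path: os.PathLike | str, one_based_inclusive: bool = True) -> list[CnvCall]:
    """Read a caller-output TSV (sample, chrom, start, end, state, caller).

    An optional ``segment_mean`` column is carried through. Coordinates are
    converted from 1-based inclusive (the default declaration) to 0-based
    half-open.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample", "chrom", "start", "end", "state", "caller"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    calls = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end < start:
            raise DataError(f"{path}: inverted interval {row.chrom}:{start}-{end}")
        if one_based_inclusive:
            start, end = start - 1, end
        mean = None
        if "segment_mean" in df.columns:
            raw = getattr(row, "segment_mean")
            if raw is not None and not pd.isna(raw):
                mean = float(raw)
        calls.append(
            CnvCall(
                sample_id=str(row.sample),
                interval=GenomicInterval(str(row.chrom), start, end),
                state=_state_from_token(str(row.state)),
                caller=str(row.caller),
                segment_mean=mean,
            )
        )
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: os.PathLike | str) -> None:
    """Write calls as the TSV dialect `read_cnv_calls` expects (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tstate\tcaller\tsegment_mean\n")
        for c in calls:
            mean = "" if c.segment_mean is None else f"{c.segment_mean:g}"
            fh.write(
                f"{c.sample_id}\t{c.interval.chrom}\t{c.interval.start + 1}\t"
                f"{c.interval.end}\t{c.state}\t{c.caller}\t{mean}\n"
            )


# ---------------------------------------------------------------------------
# BED


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: os.PathLike | str,
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence[float]] = None,
) -> None:
    """Write BED3 (or BED5 when names are given); sorted by (chrom, start)."""
    items = list(intervals)
    names = list(names) if names is not None else None
    scores = list(scores) if scores is not None else None
    order = sorted(range(len(items)), key=lambda i: items[i].sort_key())
    with open(path, "w") as fh:
        for i in order:
            iv = items[i]
            line = f"{iv.chrom}\t{iv.start}\t{iv.end}"
            if names is not None:
                score = scores[i] if scores is not None else 0
                line += f"\t{names[i]}\t{score:g}" if isinstance(score, float) else f"\t{names[i]}\t{score}"
            fh.write(line + "\n")


def read_bed(path: os.PathLike | str) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet` (extra columns ignored)."""
    return IntervalSet(iv for iv, _, _ in iter_bed(path))


def iter_bed(path: os.PathLike | str):
    """Yield (interval, name, score) triples; name/score None for BED3."""
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {ln}: fewer than 3 BED columns")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            name = fields[3].strip() if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 else None
            yield iv, name, score


# ---------------------------------------------------------------------------
# Intensity (final-report-like) TSV


def read_intensity_table(path: os.PathLike | str, marker_map: MarkerMap) -> IntensityTable:
    """Read a long-format TSV (marker_id, sample_id, baf, lrr).

    An Illumina-final-report-style ``[Header]`` block is tolerated: lines
    before a ``[Data]`` marker are skipped.
    """
    with open(path) as fh:
        text = fh.read()
    if "[Data]" in text:
        text = text.split("[Data]", 1)[1].lstrip("\n")
    df = pd.read_csv(io.StringIO(text), sep="\t")
    required = ["marker_id", "sample_id", "baf", "lrr"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    sample_ids = sorted(df["sample_id"].astype(str).unique())
    m_index = {mid: i for i, mid in enumerate(marker_map.marker_id)}
    s_index = {sid: j for j, sid in enumerate(sample_ids)}
    shape = (len(marker_map), len(sample_ids))
    baf = np.full(shape, np.nan)
    lrr = np.full(shape, np.nan)
    for row in df.itertuples(index=False):
        try:
            i = m_index[str(row.marker_id)]
        except KeyError:
            raise DataError(f"{path}: unknown marker {row.marker_id!r}")
        j = s_index[str(row.sample_id)]
        baf[i, j] = float(row.baf)
        lrr[i, j] = float(row.lrr)
    return IntensityTable(marker_map, sample_ids, baf, lrr)


def write_intensity_table(table: IntensityTable, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tsample_id\tbaf\tlrr\n")
        for i, mid in enumerate(table.marker_map.marker_id):
            for j, sid in enumerate(table.sample_ids):
                fh.write(f"{mid}\t{sid}\t{table.baf[i, j]:.6g}\t{table.lrr[i, j]:.6g}\n")


# ---------------------------------------------------------------------------
# Phased haplotypes

HAP_MISSING = -9


def write_haplotypes(
    marker_map: MarkerMap,
    sample_ids: Sequence[str],
    alleles: np.ndarray,
    path: os.PathLike | str,
) -> None:
    """Write phased alleles as TSV: chrom, pos, marker_id, then {sample}_{0,1} columns.

    ``alleles`` is (2N, n_markers); rows 2j and 2j+1 are the two chromosome
    copies of sample j.
    """
    if alleles.shape != (2 * len(sample_ids), len(marker_map)):
        raise DataError("haplotype matrix must be (2*n_samples, n_markers)")
    header = ["chrom", "pos", "marker_id"]
    for sid in sample_ids:
        header += [f"{sid}_0", f"{sid}_1"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for m in range(len(marker_map)):
            row = [str(marker_map.chrom[m]), str(marker_map.pos_bp[m]), str(marker_map.marker_id[m])]
            row += [str(int(alleles[k, m])) for k in range(alleles.shape[0])]
            fh.write("\t".join(row) + "\n")


def read_haplotypes(path: os.PathLike | str) -> tuple[MarkerMap, list[str], np.ndarray]:
    """Read the TSV written by :func:`write_haplotypes`.

    Returns (marker_map, sample_ids, alleles) with alleles shaped
    (2*n_samples, n_markers).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "marker_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos", "marker_id")]
    sample_ids = []
    for c in hap_cols:
        if not c.endswith(("_0", "_1")):
            raise ParseError(f"{path}: unexpected haplotype column {c!r}")
        sid = c[:-2]
        if sid not in sample_ids:
            sample_ids.append(sid)
    expected = [f"{sid}_{k}" for sid in sample_ids for k in (0, 1)]
    if hap_cols != expected:
        raise ParseError(f"{path}: haplotype columns must come in sample pairs")
    mm = MarkerMap(df["chrom"].astype(str), df["marker_id"].astype(str), df["pos"])
    alleles = df[hap_cols].to_numpy(dtype=np.int8).T[:, mm.input_order]
    return mm, sample_ids, alleles
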