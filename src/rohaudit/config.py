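"""Run configuration: one flat mapping of every pipeline constant.

Every constant of the audit (length-class allowances, the 0.3
segmentation-mean threshold, the 99th island percentile, the 9.2365 kb
BovineHD fence, the 1 Mb permutation spacing, 10,000 randomizations, the
100-kb block size, the 2511 Mb genome denominator) is a named,
overridable key; the defaults are the published parameterization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .genotype_qc import QcThresholds
from .roh_detection import DEFAULT_ROH_CLASSES, RohClassParams


@dataclass
class RunConfig:
    # inputs
    ped_path: Optional[str] = None
    map_path: Optional[str] = None
    cnv_calls_a: Optional[str] = None
    cnv_calls_b: Optional[str] = None
    haplotypes_path: Optional[str] = None
    outdir: str = "rohaudit_out"

    # QC
    max_marker_missing: float = 0.05
    max_sample_missing: float = 0.10
    min_sample_call_rate: float = 0.90
    hwe_alpha: float = 0.001

    # ROH
    roh_classes: tuple[RohClassParams, ...] = DEFAULT_ROH_CLASSES
    froh_denominator_bp: Optional[int] = None  # None: sum of observed chromosome spans

    # islands
    island_percentile: float = 99.0
    island_min_markers: int = 2

    # CNV / CNVR
    coords_one_based_inclusive: bool = True
    segment_mean_threshold: float = 0.3
    call_merge_gap_fraction: float = 0.2
    exclude_outlier_samples: bool = True
    consensus: bool = True

    # coverage gaps
    fence_override_bp: Optional[float] = None  # None: Tukey fence from the map
    gaps_on_raw_map: bool = True  # chip-map property; False: use the post-QC map

    # audit / permutation
    cnvr_source: str = "consensus"
    permutation_categories: tuple[str, ...] = ("loss", "both")
    n_permutations: int = 10_000
    permutation_min_gap_bp: int = 1_000_000
    gain_as_artefact: bool = False

    # haplotype diversity
    block_size_bp: int = 100_000
    block_min_markers: int = 2
    breed: str = "breed1"

    seed: int = 0

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(
            max_marker_missing=self.max_marker_missing,
            max_sample_missing=self.max_sample_missing,
            min_sample_call_rate=self.min_sample_call_rate,
            hwe_alpha=self.hwe_alpha,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roh_classes"] = [dataclasses.asdict(c) for c in self.roh_classes]
        d["permutation_categories"] = list(self.permutation_categories)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "roh_classes" in d:
            d["roh_classes"] = tuple(
                RohClassParams(**c) if isinstance(c, dict) else c for c in d["roh_classes"]
            )
        if "permutation_categories" in d:
            d["permutation_categories"] = tuple(d["permutation_categories"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
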