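"""Analysis thresholds shared across the pipeline.

All tunables of the haplotype analysis live in one dataclass so a single
YAML file can drive every stage (variant selection, windowing, grouping,
Yin/Yang and Mosaic calling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import yaml

#: Continent order used for deterministic tie-breaking throughout.
DEFAULT_CONTINENTS: tuple[str, ...] = ("AFR", "AMR", "ASN", "EUR")


@dataclass
class AnalysisConfig:
    """Thresholds for the haplotype-classification pipeline.

    maf_threshold
        A variant is "frequent" iff min(f, 1-f) > maf_threshold (strict).
    k
        Number of adjacent frequent variants per segment haplotype.
    window_bp
        Spacing of window anchors along each chromosome (0-based grid).
    max_intra_diff
        Haplotypes within this Hamming distance of a group representative
        are absorbed into the group (tolerates a few sequencing errors).
    min_count / min_freq
        Common-haplotype threshold, as an absolute occurrence count or a
        frequency of the 2n sampled haplotypes.  Exactly one is active.
    min_diff
        Minimum Hamming distance between two common haplotypes for them to
        form a mutually exclusive (Yin/Yang) pair.
    mosaic_threshold
        Minimum number of Yin/Yang pieces for a haplotype to be called Mosaic.
    snp_only
        Drop biallelic indels, keeping SNPs only.
    dedup_segments
        Drop a window whose selected variant set is identical to the
        previous window's (elongation overruns can duplicate segments).
    """

    maf_threshold: float = 0.25
    k: int = 50
    window_bp: int = 500_000
    max_intra_diff: int = 2
    min_count: Optional[int] = 100
    min_freq: Optional[float] = None
    min_diff: int = 47
    mosaic_threshold: int = 12
    snp_only: bool = False
    dedup_segments: bool = False
    continents: Sequence[str] = field(default_factory=lambda: DEFAULT_CONTINENTS)

    def __post_init__(self) -> None:
        if (self.min_count is None) == (self.min_freq is None):
            raise ValueError("exactly one of min_count / min_freq must be set")
        if not 0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path, section: str = "analysis") -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if section in doc:
            doc = doc[section]
        names = {f.name for f in fields(cls)}
        unknown = set(doc) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "continents" in doc:
            doc["continents"] = tuple(doc["continents"])
        return cls(**doc)
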