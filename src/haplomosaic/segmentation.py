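"""Select frequent variants and window them into 50-variant segments.

Each chromosome is overlaid with a fixed grid of window anchors spaced
``window_bp`` apart (0-based, anchored at position 0).  For every anchor
``s`` the segment is the first ``k`` frequent variants with 1-based
position strictly greater than ``s``; if fewer than ``k`` frequent
variants remain downstream, the window emits nothing.  A segment may
extend well past the next anchor (elongation), so segments from
successive windows can overlap or even coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .variant_io import PhasedCohort

__all__ = [
    "SegmentSpec",
    "select_frequent",
    "build_segments",
    "extract_haplotypes",
    "write_segment_table",
]


@dataclass(frozen=True)
class SegmentSpec:
    """One window's selection of ``k`` adjacent frequent variants.

    ``gv_indices`` index into the cohort's variant list and are adjacent
    within the frequent-variant subsequence.  ``start_pos``/``end_pos``
    are the 1-based positions of the first and last selected variant;
    ``length_kb`` is their distance in kilobases.
    """

    chrom: str
    window_index: int
    window_start: int  # 0-based multiple of window_bp
    gv_indices: tuple[int, ...]
    start_pos: int
    end_pos: int

    @property
    def length_kb(self) -> float:
        return (self.end_pos - self.start_pos) / 1000.0

    @property
    def k(self) -> int:
        return len(self.gv_indices)


def select_frequent(
    cohort: PhasedCohort, maf_threshold: float = 0.25
) -> np.ndarray:
    """Indices of variants with minor allele frequency strictly above threshold."""
    n_hap = cohort.n_haplotypes
    if n_hap == 0:
        raise ValueError("cohort has no samples")
    counts = np.array([r.alt_count for r in cohort.records], dtype=np.float64)
    f = counts / n_hap
    maf = np.minimum(f, 1.0 - f)
    return np.nonzero(maf > maf_threshold)[0]


def build_segments(
    cohort: PhasedCohort,
    window_bp: int = 500_000,
    k: int = 50,
    maf_threshold: float = 0.25,
    dedup: bool = False,
) -> list[SegmentSpec]:
    """Build the per-window segments of ``k`` adjacent frequent variants.

    With ``dedup`` set, a window whose selected variant set is identical to
    the previous window's is dropped.
    """
    freq_idx = select_frequent(cohort, maf_threshold)
    positions = cohort.positions
    chroms = cohort.chroms
    segments: list[SegmentSpec] = []
    for chrom in pd.unique(chroms):
        on_chrom = freq_idx[chroms[freq_idx] == chrom]
        if len(on_chrom) < k:
            continue
        pos = positions[on_chrom]
        last_start = pos[-k]  # last frequent variant that can head a full segment
        window_index = 0
        prev: Optional[tuple[int, ...]] = None
        s = 0
        while s < last_start:  # need pos > s for the segment head
            j = int(np.searchsorted(pos, s, side="right"))
            if j + k > len(on_chrom):
                break
            gv = tuple(int(i) for i in on_chrom[j : j + k])
            if not (dedup and gv == prev):
                segments.append(
                    SegmentSpec(
                        chrom=str(chrom),
                        window_index=window_index,
                        window_start=s,
                        gv_indices=gv,
                        start_pos=int(positions[gv[0]]),
                        end_pos=int(positions[gv[-1]]),
                    )
                )
            prev = gv
            window_index += 1
            s += window_bp
    return segments


def extract_haplotypes(cohort: PhasedCohort, seg: SegmentSpec) -> list[str]:
    """The 2n length-k haplotype strings of a segment, in genomic order."""
    sub = cohort.alleles[list(seg.gv_indices), :]
    return ["".join(col) for col in sub.astype("U1").T]


def write_segment_table(
    segments: Sequence[SegmentSpec], path: str | Path
) -> pd.DataFrame:
    """TSV of (chrom, segment_index, start_pos, length_kb, n_frequent_gvs)."""
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "segment_index": [s.window_index for s in segments],
            "start_pos": [s.start_pos for s in segments],
            "length_kb": [s.length_kb for s in segments],
            "n_frequent_gvs": [s.k for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def segments_from_config(cohort: PhasedCohort, cfg: AnalysisConfig) -> list[SegmentSpec]:
    return build_segments(
        cohort,
        window_bp=cfg.window_bp,
        k=cfg.k,
        maf_threshold=cfg.maf_threshold,
        dedup=cfg.dedup_segments,
    )
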