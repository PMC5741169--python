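"""Common haplotypes, Yin/Yang pairs, and Mosaic decomposition.

The 2n haplotype strings of a segment are grouped by near-identity
(Hamming distance <= 2 to a group representative); groups reaching the
occurrence threshold are common haplotypes (CHs).  Mutually exclusive CH
pairs that differ at >= 47 of 50 positions are Yin/Yang pairs (Yin the
more frequent).  A remaining CH is Mosaic if rebuilding it from Yin and
Yang fragments requires at least 12 pieces — the minimal number of
maximal runs over any resolution of wildcard positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Optional, Sequence

import numpy as np

from .config import AnalysisConfig

__all__ = [
    "HaplotypeGroup",
    "CHSet",
    "YinYangPair",
    "MosaicResult",
    "hamming",
    "group_haplotypes",
    "common_haplotypes",
    "find_yinyang",
    "min_pieces",
    "derived_fraction",
    "mosaic_source_split",
    "expected_split_null",
    "segment_summary",
    "AllStatusesUnknownError",
]


class AllStatusesUnknownError(ValueError):
    """Raised when a derived fraction is requested but every position is X."""


def hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _bits(s: str) -> int:
    return int(s, 2) if s else 0


@dataclass
class HaplotypeGroup:
    """A near-identity haplotype group.

    The representative is the member with the highest exact count (ties
    broken lexicographically by the grouping scan order); every member is
    within the configured Hamming distance of it.
    """

    representative: str
    members: dict[str, int] = field(default_factory=dict)
    continent_counts: dict[str, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return sum(self.members.values())


@dataclass
class CHSet:
    """Haplotype groups of one segment, ranked by (count desc, rep asc)."""

    groups: list[HaplotypeGroup]
    n_haplotypes: int
    max_intra_diff: int

    def __len__(self) -> int:
        return len(self.groups)

    def rerank(self) -> None:
        self.groups.sort(key=lambda g: (-g.count, g.representative))


@dataclass(frozen=True)
class YinYangPair:
    """A mutually exclusive CH pair; Yin is the more frequent member."""

    yin: HaplotypeGroup
    yang: HaplotypeGroup

    @property
    def n_diff(self) -> int:
        return hamming(self.yin.representative, self.yang.representative)


@dataclass(frozen=True)
class MosaicResult:
    """Minimal-piece decomposition of a haplotype against a Yin/Yang pair."""

    haplotype: str
    pieces: int
    derived_total: int
    derived_matching_yin: int
    derived_matching_yang: int
    is_mosaic: bool


def group_haplotypes(
    haps: Sequence[str],
    max_intra_diff: int = 2,
    continents: Optional[Sequence[str]] = None,
) -> CHSet:
    """Group haplotype strings by near-identity to a representative.

    Distinct strings are first counted exactly and ordered by
    (count desc, lexicographic asc).  Scanning in that order, each string
    joins the first existing group whose representative is within
    ``max_intra_diff`` differences, otherwise it founds a new group; the
    founding order guarantees the representative is the group's most
    frequent member.  Groups are finally re-ranked by total count.
    """
    if continents is not None and len(continents) != len(haps):
        raise ValueError("continents must align with haplotypes")
    counter = Counter(haps)
    lengths = {len(h) for h in counter}
    if len(lengths) > 1:
        raise ValueError(f"haplotypes have mixed lengths: {sorted(lengths)}")

    cont_counter: dict[str, Counter] = {}
    if continents is not None:
        cont_counter = {h: Counter() for h in counter}
        for h, c in zip(haps, continents):
            cont_counter[h][c] += 1

    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    groups: list[HaplotypeGroup] = []
    reps_bits: list[int] = []
    for h, c in ordered:
        hb = _bits(h)
        target: Optional[HaplotypeGroup] = None
        for g, gb in zip(groups, reps_bits):
            if (hb ^ gb).bit_count() <= max_intra_diff:
                target = g
                break
        if target is None:
            target = HaplotypeGroup(representative=h)
            groups.append(target)
            reps_bits.append(hb)
        target.members[h] = c
        if continents is not None:
            for cont, n in cont_counter[h].items():
                target.continent_counts[cont] = (
                    target.continent_counts.get(cont, 0) + n
                )
    chset = CHSet(
        groups=groups, n_haplotypes=len(haps), max_intra_diff=max_intra_diff
    )
    chset.rerank()
    return chset


def common_haplotypes(
    chset: CHSet,
    min_count: Optional[int] = None,
    min_freq: Optional[float] = None,
) -> list[HaplotypeGroup]:
    """Groups reaching the CH threshold, by count or by frequency of 2n."""
    if (min_count is None) == (min_freq is None):
        raise ValueError("supply exactly one of min_count / min_freq")
    if min_count is not None:
        return [g for g in chset.groups if g.count >= min_count]
    if chset.n_haplotypes == 0:
        return []
    return [
        g for g in chset.groups if g.count / chset.n_haplotypes >= min_freq
    ]


def find_yinyang(
    chs: Sequence[HaplotypeGroup], min_diff: int = 47
) -> list[YinYangPair]:
    """Greedy pairing of mutually exclusive CHs by rank.

    The most frequent unpaired CH is paired with the most frequent other
    unpaired CH at Hamming distance >= ``min_diff``; both leave the pool
    and the scan repeats.  Within a pair, Yin is the higher-count member.
    """
    pool = list(chs)
    pairs: list[YinYangPair] = []
    i = 0
    while i < len(pool):
        a = pool[i]
        partner_j = None
        for j in range(i + 1, len(pool)):
            if hamming(a.representative, pool[j].representative) >= min_diff:
                partner_j = j
                break
        if partner_j is None:
            i += 1
            continue
        b = pool.pop(partner_j)
        pool.pop(i)
        yin, yang = (a, b) if a.count >= b.count else (b, a)
        pairs.append(YinYangPair(yin=yin, yang=yang))
    return pairs


def _piece_labels(h: str, yin: str, yang: str) -> str:
    """Per-position labels: Y matches yin only, G matches yang only, else '.'"""
    if not (len(h) == len(yin) == len(yang)):
        raise ValueError("h, yin, yang must have equal lengths")
    out = []
    for hc, yc, gc in zip(h, yin, yang):
        my, mg = hc == yc, hc == gc
        if my and not mg:
            out.append("Y")
        elif mg and not my:
            out.append("G")
        else:
            out.append(".")  # wildcard: matches both (yin==yang) or neither
    return "".join(out)


def min_pieces(h: str, yin: str, yang: str) -> int:
    """Minimal number of Yin/Yang fragments needed to rebuild ``h``.

    Wildcard positions (where yin and yang agree, or where ``h`` matches
    neither) never force a breakpoint; with them removed, the answer is
    one plus the number of Y<->G alternations in the remaining label
    sequence, which is the minimum over all wildcard resolutions.
    """
    labels = _piece_labels(h, yin, yang).replace(".", "")
    if not labels:
        return 1
    pieces = 1
    for prev, cur in zip(labels, labels[1:]):
        if cur != prev:
            pieces += 1
    return pieces


def derived_fraction(h: str, statuses: Sequence[str]) -> float:
    """Fraction of derived alleles among positions with known ancestral status.

    A position is derived when the haplotype carries the non-ancestral
    allele: allele 1 where the reference is ancestral (R), or allele 0
    where the alternative is ancestral (M).  X positions are excluded
    from numerator and denominator.
    """
    if len(h) != len(statuses):
        raise ValueError("haplotype and status vector must have equal lengths")
    derived = 0
    known = 0
    for allele, st in zip(h, statuses):
        if st == "X":
            continue
        known += 1
        if (allele == "1" and st == "R") or (allele == "0" and st == "M"):
            derived += 1
    if known == 0:
        raise AllStatusesUnknownError(
            "derived fraction undefined: ancestral status unknown at every position"
        )
    return derived / known


def derived_count(h: str, statuses: Sequence[str]) -> int:
    """Number of derived alleles among non-X positions."""
    return sum(
        1
        for allele, st in zip(h, statuses)
        if st != "X"
        and ((allele == "1" and st == "R") or (allele == "0" and st == "M"))
    )


def mosaic_source_split(
    mosaic: str, yin: str, yang: str, statuses: Sequence[str]
) -> tuple[int, int, int]:
    """Attribute each derived Mosaic allele to Yin, Yang, or neither.

    At positions where yin != yang, the derived allele is credited to
    whichever of the two carries it; derived alleles at yin == yang
    positions go to the "other" bucket.
    """
    n_yin = n_yang = n_other = 0
    for m, y, g, st in zip(mosaic, yin, yang, statuses):
        if st == "X":
            continue
        is_derived = (m == "1" and st == "R") or (m == "0" and st == "M")
        if not is_derived:
            continue
        if y == g:
            n_other += 1
        elif m == y:
            n_yin += 1
        else:
            n_yang += 1
    return n_yin, n_yang, n_other


def expected_split_null(
    n_derived: int,
    p_yin: float = 0.546,
    p_yang: float = 0.438,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    one_side_threshold: float = 0.8,
) -> float:
    """Null fraction of segments with a one-sided derived-allele split.

    Each replicate assigns ``n_derived`` alleles independently to Yin,
    Yang, or neither with probabilities (p_yin, p_yang, 1-p_yin-p_yang),
    and counts as one-sided when at least ``one_side_threshold`` of the
    alleles fall on a single side.  Returns the fraction of one-sided
    replicates.
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    if n_derived <= 0:
        raise ValueError("n_derived must be positive")
    if p_yin < 0 or p_yang < 0 or p_yin + p_yang > 1 + 1e-12:
        raise ValueError("need p_yin, p_yang >= 0 and p_yin + p_yang <= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p_other = max(0.0, 1.0 - p_yin - p_yang)
    draws = rng.multinomial(n_derived, [p_yin, p_yang, p_other], size=reps)
    max_side = draws[:, :2].max(axis=1)
    return float(np.mean(max_side >= one_side_threshold * n_derived))


@dataclass
class SegmentClassification:
    """Full classification of one segment."""

    chset: CHSet
    chs: list[HaplotypeGroup]
    pairs: list[YinYangPair]
    mosaics: dict[str, MosaicResult]  # keyed by CH representative


def classify_segment(
    haps: Sequence[str],
    statuses: Sequence[str],
    cfg: AnalysisConfig,
    continents: Optional[Sequence[str]] = None,
) -> SegmentClassification:
    """Run grouping, CH calling, Yin/Yang pairing, and Mosaic decomposition."""
    chset = group_haplotypes(haps, cfg.max_intra_diff, continents)
    chs = common_haplotypes(chset, min_count=cfg.min_count, min_freq=cfg.min_freq)
    pairs = find_yinyang(chs, cfg.min_diff)
    mosaics: dict[str, MosaicResult] = {}
    if pairs:
        yin = pairs[0].yin.representative
        yang = pairs[0].yang.representative
        paired = {p.yin.representative for p in pairs} | {
            p.yang.representative for p in pairs
        }
        for g in chs:
            rep = g.representative
            if rep in paired:
                continue
            pieces = min_pieces(rep, yin, yang)
            n_yin, n_yang, n_other = mosaic_source_split(rep, yin, yang, statuses)
            mosaics[rep] = MosaicResult(
                haplotype=rep,
                pieces=pieces,
                derived_total=n_yin + n_yang + n_other,
                derived_matching_yin=n_yin,
                derived_matching_yang=n_yang,
                is_mosaic=pieces >= cfg.mosaic_threshold,
            )
    return SegmentClassification(chset=chset, chs=chs, pairs=pairs, mosaics=mosaics)


def segment_summary(
    seg,
    classification: SegmentClassification,
    statuses: Sequence[str],
) -> dict:
    """One summary row per segment (chrom, bounds, CH/Yin-Yang statistics).

    ``max_diff`` is "NA" for segments with fewer than two CHs.  Per-CH
    derived-allele and piece counts are attached for downstream tables.
    """
    chs = classification.chs
    if len(chs) >= 2:
        max_diff: object = max(
            hamming(a.representative, b.representative)
            for i, a in enumerate(chs)
            for b in chs[i + 1 :]
        )
    else:
        max_diff = "NA"
    per_ch = []
    for g in chs:
        entry = {
            "representative": g.representative,
            "count": g.count,
            "derived": derived_count(g.representative, statuses),
        }
        mres = classification.mosaics.get(g.representative)
        if mres is not None:
            entry["pieces"] = mres.pieces
            entry["is_mosaic"] = mres.is_mosaic
        per_ch.append(entry)
    return {
        "chrom": seg.chrom,
        "segment_index": seg.window_index,
        "start_pos": seg.start_pos,
        "length_kb": seg.length_kb,
        "n_ch": len(chs),
        "total_ch_occurrences": sum(g.count for g in chs),
        "max_diff": max_diff,
        "n_yinyang_ch": 2 * len(classification.pairs),
        "n_mosaic_ch": sum(
            m.is_mosaic for m in classification.mosaics.values()
        ),
        "per_ch": per_ch,
    }
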