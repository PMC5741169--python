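"""Deduced ancestral haplotypes and archaic-diplotype comparison.

For each segment the 100%-ancestral haplotype is read off the per-variant
ancestral statuses (R -> 0, M -> 1, X -> masked).  Its matches in the
cohort (<= 2 mismatches over unmasked positions) are classified by
abundance (absent / rare 1-3 / uncommon 4-99 / common >= 100) and by
continental specificity.  An archaic individual, being almost entirely
homozygous at frequent variants, is collapsed from diplotype codes to a
single haplotype and compared with the segment's common haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .haplotype_classes import HaplotypeGroup, derived_fraction
from .variant_io import ArchaicDiplotype
from .config import DEFAULT_CONTINENTS

__all__ = [
    "AncestralProfile",
    "AbundanceClass",
    "MatchResult",
    "ancestral_haplotype",
    "match_ancestral",
    "classify_abundance",
    "classify_specificity",
    "normalize_by_continent",
    "archaic_to_haplotype",
    "compare_archaic",
    "ArchaicComparison",
]

MASK = "."  # masked (unknown ancestral state) position in a profile


@dataclass(frozen=True)
class AncestralProfile:
    """Per-position ancestral allele: '0', '1', or '.' where unknown."""

    profile: str

    @property
    def n_masked(self) -> int:
        return self.profile.count(MASK)

    def __len__(self) -> int:
        return len(self.profile)


@dataclass(frozen=True)
class AbundanceClass:
    """Abundance of ancestral-haplotype matches in a segment."""

    label: str  # absent | rare | uncommon | common
    match_count: int

    _BOUNDS = (("absent", 0, 0), ("rare", 1, 3), ("uncommon", 4, 99))

    @classmethod
    def from_count(cls, n: int) -> "AbundanceClass":
        if n < 0:
            raise ValueError("match count must be >= 0")
        for label, lo, hi in cls._BOUNDS:
            if lo <= n <= hi:
                return cls(label, n)
        return cls("common", n)


def ancestral_haplotype(statuses: Sequence[str]) -> AncestralProfile:
    """Deduce the 100%-ancestral haplotype from per-variant statuses."""
    mapping = {"R": "0", "M": "1", "X": MASK}
    try:
        return AncestralProfile("".join(mapping[s] for s in statuses))
    except KeyError as exc:
        raise ValueError(f"bad ancestral status {exc.args[0]!r}") from None


@dataclass
class MatchResult:
    """Ancestral-haplotype matches of one segment."""

    eligible: bool
    count: int
    per_continent: dict[str, int]
    abundance: Optional[AbundanceClass]


def match_ancestral(
    haps: Sequence[str],
    profile: AncestralProfile,
    max_diff: int = 2,
    continents: Optional[Sequence[str]] = None,
) -> MatchResult:
    """Count cohort haplotypes within ``max_diff`` of the ancestral profile.

    Mismatches are counted over unmasked positions only.  Segments with
    more than half of their positions masked are flagged ineligible (the
    <=2-difference rule would be meaningless there).
    """
    unmasked = [i for i, c in enumerate(profile.profile) if c != MASK]
    if len(unmasked) * 2 < len(profile):
        return MatchResult(False, 0, {}, None)
    count = 0
    per_continent: dict[str, int] = {}
    for j, h in enumerate(haps):
        if len(h) != len(profile):
            raise ValueError("haplotype/profile length mismatch")
        mism = sum(1 for i in unmasked if h[i] != profile.profile[i])
        if mism <= max_diff:
            count += 1
            if continents is not None:
                c = continents[j]
                per_continent[c] = per_continent.get(c, 0) + 1
    return MatchResult(True, count, per_continent, AbundanceClass.from_count(count))


def classify_abundance(match_count: int) -> AbundanceClass:
    return AbundanceClass.from_count(match_count)


def normalize_by_continent(
    counts: dict[str, int],
    panel: dict[str, tuple[str, str]],
    continent_order: Sequence[str] = DEFAULT_CONTINENTS,
) -> tuple[dict[str, float], str]:
    """Per-capita match rates (count / 2 x continent samples) and the
    predominant continent; rate ties break on the configured order."""
    sizes: dict[str, int] = {}
    for _, (_, cont) in panel.items():
        sizes[cont] = sizes.get(cont, 0) + 1
    rates: dict[str, float] = {}
    for cont in continent_order:
        if cont in sizes:
            rates[cont] = counts.get(cont, 0) / (2 * sizes[cont])
    for cont in counts:
        if cont not in rates:
            raise ValueError(f"continent {cont!r} absent from panel/order")
    predominant = max(rates, key=lambda c: (rates[c], -list(continent_order).index(c)))
    return rates, predominant


def classify_specificity(
    per_continent_counts: dict[str, int],
    cls: AbundanceClass,
    panel: Optional[dict[str, tuple[str, str]]] = None,
    continent_order: Sequence[str] = DEFAULT_CONTINENTS,
) -> str:
    """Continental specificity of ancestral-haplotype matches.

    Rare haplotypes are continent-specific only when a single continent
    holds 100% of matches; uncommon when one holds strictly more than 90%.
    Common haplotypes use per-capita predominance instead (requires the
    panel).  Everything else is "multi-continent".
    """
    total = sum(per_continent_counts.values())
    if cls.label == "absent" or total == 0:
        return "absent"
    if cls.label == "rare":
        for cont, n in per_continent_counts.items():
            if n == total:
                return cont
        return "multi-continent"
    if cls.label == "uncommon":
        for cont, n in per_continent_counts.items():
            if n / total > 0.9:
                return cont
        return "multi-continent"
    if panel is None:
        raise ValueError("common-class specificity needs the sample panel")
    _, predominant = normalize_by_continent(
        per_continent_counts, panel, continent_order
    )
    return predominant


def archaic_to_haplotype(d: ArchaicDiplotype) -> str:
    """Collapse homozygous diplotype codes to a haplotype string.

    0 -> '0', 2 -> '1'; heterozygous (1) and unresolved (x) positions
    become missing ('.').
    """
    mapping = {"0": "0", "2": "1", "1": ".", "x": "."}
    return "".join(mapping[c] for c in d.codes)


@dataclass
class ArchaicComparison:
    """Archaic-vs-CH comparison for one segment."""

    excluded: bool
    n_resolved: int
    diffs: dict[str, int]  # CH representative -> differences over resolved sites
    near_identical: dict[str, bool]
    archaic_derived_fraction: Optional[float]


def compare_archaic(
    archaic_hap: str,
    chs: Sequence[HaplotypeGroup],
    statuses: Sequence[str],
    max_diff: int = 2,
    min_resolved: int = 45,
) -> ArchaicComparison:
    """Compare an archaic haplotype with a segment's common haplotypes.

    Differences are counted over positions resolved in the archaic
    haplotype; a segment with fewer than ``min_resolved`` resolved
    positions is excluded.  The archaic derived-allele fraction is
    computed over resolved, status-known positions.
    """
    resolved = [i for i, c in enumerate(archaic_hap) if c != "."]
    if len(resolved) < min_resolved:
        return ArchaicComparison(True, len(resolved), {}, {}, None)
    diffs: dict[str, int] = {}
    near: dict[str, bool] = {}
    for g in chs:
        rep = g.representative
        if len(rep) != len(archaic_hap):
            raise ValueError("archaic haplotype/CH length mismatch")
        d = sum(1 for i in resolved if rep[i] != archaic_hap[i])
        diffs[rep] = d
        near[rep] = d <= max_diff
    sub_h = "".join(archaic_hap[i] for i in resolved)
    sub_st = [statuses[i] for i in resolved]
    try:
        frac = derived_fraction(sub_h, sub_st)
    except ValueError:
        frac = None
    return ArchaicComparison(False, len(resolved), diffs, near, frac)
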