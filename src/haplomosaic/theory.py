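"""Closed-form population-genetic calculators.

Back-of-the-envelope arithmetic for the admixture argument: the fixation
clock (k = 2*mu fixed mutations per generation for a per-gamete mutation
rate mu), diversity-based effective population size (theta = 4*mu*N_eff),
a linear derived-allele clock calibrated on an archaic reference genome,
and the frequent-variant yield of merging two long-separated lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ClockCalibration",
    "fixation_rate",
    "generations_to_fix",
    "to_years",
    "neff_from_theta",
    "derived_clock",
    "admixture_yield",
]


@dataclass(frozen=True)
class ClockCalibration:
    """Calibration of the linear derived-allele clock.

    ``f_modern`` is the present-day derived-allele fraction at frequent
    variants (≈0.50 as a first approximation), ``f_archaic`` the fraction
    observed in the archaic reference (0.18), and ``t_archaic`` the
    modern/archaic separation time in Mya (0.7).  ``generation_time`` is
    in years.
    """

    f_modern: float = 0.50
    f_archaic: float = 0.18
    t_archaic: float = 0.7
    generation_time: float = 25.0

    def __post_init__(self) -> None:
        if not 0 <= self.f_archaic < self.f_modern <= 1:
            raise ValueError("need 0 <= f_archaic < f_modern <= 1")
        if self.t_archaic <= 0:
            raise ValueError("t_archaic must be positive")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")


def fixation_rate(mu_per_gamete: float) -> float:
    """Fixed mutations per generation, k = 2*mu for per-gamete rate mu."""
    if mu_per_gamete < 0:
        raise ValueError("mutation rate must be >= 0")
    return 2.0 * mu_per_gamete


def generations_to_fix(n_mutations: float, k: float) -> float:
    """Generations needed to fix ``n_mutations`` at rate ``k`` per generation."""
    if k <= 0:
        raise ValueError("fixation rate must be positive")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    return n_mutations / k


def to_years(generations: float, generation_time: float = 25.0) -> float:
    """Convert generations to years."""
    return generations * generation_time


def neff_from_theta(theta: float, mu_per_person: float) -> float:
    """Effective population size from diversity: N_eff = theta / (4*mu)."""
    if mu_per_person <= 0:
        raise ValueError("mutation rate must be positive")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return theta / (4.0 * mu_per_person)


def derived_clock(f: float, cal: ClockCalibration = ClockCalibration()) -> float:
    """Time (Mya) at which the derived-allele fraction was ``f``.

    Assumes a linear decline of the derived fraction backwards in time,
    anchored at (0, f_modern) and (t_archaic, f_archaic):

        t(f) = t_archaic * (f_modern - f) / (f_modern - f_archaic)
    """
    if not 0 <= f <= cal.f_modern:
        raise ValueError(
            f"derived fraction {f} outside [0, f_modern={cal.f_modern}]"
        )
    return cal.t_archaic * (cal.f_modern - f) / (cal.f_modern - cal.f_archaic)


def admixture_yield(
    separation_years: float,
    k: float = 100.0,
    generation_time: float = 25.0,
    n_lineages: int = 2,
) -> float:
    """Frequent variants created by admixing long-separated lineages.

    Each lineage fixes ``k`` mutations per generation during separation;
    merging converts every lineage-private fixed difference into a
    frequent variant of the pooled population.
    """
    if separation_years < 0:
        raise ValueError("separation time must be >= 0")
    return n_lineages * (separation_years / generation_time) * k


def discussion_report(cal: ClockCalibration = ClockCalibration()) -> dict[str, float]:
    """All headline closed-form quantities in one labelled mapping."""
    k = fixation_rate(50.0)
    return {
        "fixation_rate_k_mu50": k,
        "generations_per_1e6_fixations": generations_to_fix(1e6, k),
        "years_per_1e6_fixations": to_years(
            generations_to_fix(1e6, k), cal.generation_time
        ),
        "neff_theta4e6_mu100": neff_from_theta(4e6, 100.0),
        "mosaic_formation_mya": derived_clock(0.31, cal),
        "lineage_separation_mya": derived_clock(0.0, cal),
        "lineage_vs_archaic_ratio": derived_clock(0.0, cal) / cal.t_archaic,
        "admixture_frequent_gv_yield": admixture_yield(
            to_years(generations_to_fix(1e6, k), cal.generation_time),
            k,
            cal.generation_time,
        ),
    }
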