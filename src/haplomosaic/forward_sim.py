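"""Forward-time simulation of a diploid population with mutation influx,
crossover recombination, permanent-pair mating, and truncation selection.

The genome is an abstract continuous interval [0, L) under the
infinite-sites assumption: every new mutation gets a fresh uniform
position.  Each generation the N diploids are paired at random into N/2
permanent pairs; every pair produces ``alpha`` offspring, each built from
two fresh gametes (one per parent, with exactly ``r`` uniform crossovers
and Poisson(mu) new mutations); the offspring are ranked by multiplicative
fitness and the top N survive.  With ``alpha = 2`` every offspring
survives and the dynamics are pure drift.

Fitness is co-dominant: a mutation with coefficient s multiplies fitness
by (1 - h*s) when heterozygous and (1 - s) when homozygous (s > 0
deleterious, s < 0 beneficial, s = 0 neutral).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from . import haplotype_classes as hc

__all__ = [
    "SimConfig",
    "SimStats",
    "MutationRegistry",
    "ForwardSimulator",
    "make_gamete",
    "fitness",
    "run",
    "analyze_population",
    "PopulationHaplotypeStats",
    "admixture_experiment",
    "AdmixtureResult",
    "sweep_population_size",
]

_LINEAGE_ID_STRIDE = 10**12  # disjoint mutation-id blocks for split lineages


@dataclass
class SimConfig:
    """Forward-simulation parameters.

    ``mu`` is the mean number of new mutations per gamete; ``r`` the exact
    number of crossovers per gamete; ``alpha`` the number of offspring per
    pair (two gives no selection).  ``effect_mix`` = (p_del, p_ben, p_neu)
    gives the category probabilities for new mutations, with exponential
    effect magnitudes of means ``s_del_mean`` / ``s_ben_mean``.
    """

    N: int = 100
    r: int = 2
    alpha: int = 2
    mu: float = 5.0
    h: float = 0.5
    p_del: float = 0.81
    p_ben: float = 0.09
    p_neu: float = 0.10
    s_del_mean: float = 1e-3
    s_ben_mean: float = 1e-3
    L: float = 1.0
    generations: int = 100
    burn_in: int = 0
    seed: int = 0
    alpha_per_individual: bool = False
    max_segregating: int = 2_000_000
    track_registry: bool = False

    def __post_init__(self) -> None:
        if self.N <= 0 or self.N % 2:
            raise ValueError("N must be a positive even number (pair mating)")
        if self.alpha < 2:
            raise ValueError("alpha must be >= 2 (population cannot shrink)")
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if abs(self.p_del + self.p_ben + self.p_neu - 1.0) > 1e-9:
            raise ValueError("effect-mix probabilities must sum to 1")

    @property
    def offspring_per_pair(self) -> int:
        return 2 * self.alpha if self.alpha_per_individual else self.alpha

    def neutral(self) -> "SimConfig":
        """Copy with an all-neutral effect mix."""
        from dataclasses import replace

        return replace(self, p_del=0.0, p_ben=0.0, p_neu=1.0)


@dataclass
class SimStats:
    """Per-generation statistics collected after burn-in."""

    generation: np.ndarray
    influx: np.ndarray
    fixations: np.ndarray
    losses: np.ndarray
    segregating: np.ndarray
    frequent: np.ndarray
    cumulative_influx: int
    cumulative_fixed: int
    cumulative_lost: int
    final_segregating: int
    cohort_introduced: dict[int, int]
    cohort_lost_within: dict[int, int]
    loss_window: int
    final_sfs: np.ndarray  # counts of segregating mutations by copy number

    def fixations_per_generation(self) -> float:
        if len(self.fixations) == 0:
            return 0.0
        return float(np.mean(self.fixations))

    def early_loss_fraction(
        self, first_gen: int, last_gen: int
    ) -> float:
        """Fraction of mutations from cohorts born in [first_gen, last_gen]
        whose lineage went extinct within the tracked window of origin."""
        intro = sum(
            n for g, n in self.cohort_introduced.items() if first_gen <= g <= last_gen
        )
        lost = sum(
            n for g, n in self.cohort_lost_within.items() if first_gen <= g <= last_gen
        )
        if intro == 0:
            raise ValueError("no cohorts in the requested generation range")
        return lost / intro


@dataclass
class MutationRegistry:
    """Fate table of every mutation: position, effect, origin, count, fate."""

    table: pd.DataFrame  # id-indexed: position, s, origin, count, fate

    FATES = ("segregating", "fixed", "lost")

    def conservation_holds(self, influx: int) -> bool:
        return len(self.table) == influx


class _Population:
    """Mutable population state: a (2N, S) allele matrix over sorted sites."""

    def __init__(self, n_diploid: int):
        self.haps = np.zeros((2 * n_diploid, 0), dtype=np.uint8)
        self.pos = np.zeros(0, dtype=np.float64)
        self.s = np.zeros(0, dtype=np.float64)
        self.ids = np.zeros(0, dtype=np.int64)
        self.origin = np.zeros(0, dtype=np.int64)

    @property
    def n_diploid(self) -> int:
        return self.haps.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]

    def copy(self) -> "_Population":
        other = _Population(self.n_diploid)
        other.haps = self.haps.copy()
        other.pos = self.pos.copy()
        other.s = self.s.copy()
        other.ids = self.ids.copy()
        other.origin = self.origin.copy()
        return other


def _draw_effects(k: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    cats = rng.choice(3, size=k, p=[cfg.p_del, cfg.p_ben, cfg.p_neu])
    s = np.zeros(k)
    n_del = int(np.sum(cats == 0))
    n_ben = int(np.sum(cats == 1))
    if n_del:
        s[cats == 0] = rng.exponential(cfg.s_del_mean, n_del)
    if n_ben:
        s[cats == 1] = -rng.exponential(cfg.s_ben_mean, n_ben)
    return s


def make_gamete(
    parent_haps: np.ndarray,
    positions: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build one gamete from a parent's two haplotypes.

    Exactly ``cfg.r`` crossover points are drawn uniformly on [0, L); the
    source haplotype alternates between consecutive points, starting from
    a random one.  Poisson(mu) new mutations are then added at fresh
    uniform positions with effects from the configured mix.

    Returns (alleles over the parent's sites, new mutation positions,
    new mutation effects).
    """
    if parent_haps.shape[0] != 2:
        raise ValueError("parent must have exactly two haplotypes")
    cross = rng.uniform(0.0, cfg.L, cfg.r)
    start = int(rng.integers(0, 2))
    if cfg.r:
        parity = (start + (cross[:, None] <= positions[None, :]).sum(0)) & 1
    else:
        parity = np.full(len(positions), start, dtype=np.int64)
    alleles = np.where(parity == 0, parent_haps[0], parent_haps[1]).astype(np.uint8)
    k = int(rng.poisson(cfg.mu))
    new_pos = rng.uniform(0.0, cfg.L, k)
    new_s = _draw_effects(k, cfg, rng)
    return alleles, new_pos, new_s


def fitness(
    het: np.ndarray, hom: np.ndarray, s: np.ndarray, h: float
) -> np.ndarray:
    """Multiplicative co-dominant fitness from het/hom indicator matrices.

    ``het``/``hom`` have shape (individuals, sites); fitness is the product
    over sites of (1 - h*s) per heterozygous and (1 - s) per homozygous
    mutation, floored at zero (s >= 1 is lethal when homozygous).
    """
    # floor the per-site factors at a tiny positive value so that lethal
    # mutations (s >= 1) yield fitness 0 without 0 * -inf artifacts
    log_het = np.log(np.maximum(1.0 - h * s, 1e-300))
    log_hom = np.log(np.maximum(1.0 - s, 1e-300))
    logw = het @ log_het + hom @ log_hom
    with np.errstate(under="ignore"):
        w = np.exp(logw)
    w[logw < -600.0] = 0.0  # carries at least one (near-)lethal factor
    return w


def individual_fitness(
    ind_haps: np.ndarray, s: np.ndarray, h: float
) -> float:
    """Fitness of a single diploid from its (2, S) haplotype matrix."""
    g = ind_haps[0].astype(np.int64) + ind_haps[1].astype(np.int64)
    het = (g == 1).astype(np.float64)[None, :]
    hom = (g == 2).astype(np.float64)[None, :]
    return float(fitness(het, hom, s, h)[0])


class ForwardSimulator:
    """Stateful simulator; fully reproducible from ``cfg.seed``."""

    def __init__(self, cfg: SimConfig, rng: Optional[np.random.Generator] = None):
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.pop = _Population(cfg.N)
        self.generation = 0
        self._next_id = 0
        self.id_offset = 0
        self.cumulative_influx = 0
        self.cumulative_fixed = 0
        self.cumulative_lost = 0
        self.fixed_background: dict[int, tuple[float, float, int]] = {}
        self.cohort_introduced: dict[int, int] = {}
        self.cohort_lost_within: dict[int, int] = {}
        self.loss_window = 3
        self._gen_rows: list[tuple] = []
        self._registry_rows: list[pd.DataFrame] = []

    # -- one generation -------------------------------------------------

    def _batch_gametes(
        self, parent_idx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Gametes for the given parents (one gamete per entry)."""
        cfg, rng, pop = self.cfg, self.rng, self.pop
        G = len(parent_idx)
        S = pop.n_sites
        hapA = pop.haps[2 * parent_idx]
        hapB = pop.haps[2 * parent_idx + 1]
        start = rng.integers(0, 2, G)
        cross = rng.uniform(0.0, cfg.L, (G, cfg.r)) if cfg.r else None
        if cfg.r and S:
            # columns are position-sorted, so each crossover toggles the
            # source haplotype from its insertion index onwards; a cumsum
            # of toggle flags gives the source parity at every site
            idx = np.searchsorted(pop.pos, cross.ravel())
            flags = np.zeros((G, S + 1), dtype=np.uint8)
            np.add.at(flags, (np.repeat(np.arange(G), cfg.r), idx), 1)
            toggles = flags.cumsum(axis=1, dtype=np.uint8)[:, :S]
            parity = ((toggles + start[:, None].astype(np.uint8)) & 1).astype(bool)
        else:
            parity = np.broadcast_to((start & 1).astype(bool)[:, None], (G, S))
        gametes = np.where(parity, hapB, hapA)
        n_new = rng.poisson(cfg.mu, G)
        K = int(n_new.sum())
        new_pos = rng.uniform(0.0, cfg.L, K)
        new_s = _draw_effects(K, cfg, rng)
        owner = np.repeat(np.arange(G), n_new)
        return gametes, new_pos, new_s, owner

    def step(self) -> None:
        cfg, rng, pop = self.cfg, self.rng, self.pop
        N = cfg.N
        self.generation += 1
        g = self.generation

        perm = rng.permutation(N)
        pairs = perm.reshape(N // 2, 2)
        per_pair = cfg.offspring_per_pair
        M = per_pair * (N // 2)  # offspring before selection
        # offspring o has parents pairs[o // per_pair]; rows 2o (from parent a)
        # and 2o + 1 (from parent b)
        pair_of_off = np.repeat(np.arange(N // 2), per_pair)
        parents_a = pairs[pair_of_off, 0]
        parents_b = pairs[pair_of_off, 1]
        parent_idx = np.empty(2 * M, dtype=np.int64)
        parent_idx[0::2] = parents_a
        parent_idx[1::2] = parents_b

        gametes, new_pos, new_s, owner = self._batch_gametes(parent_idx)
        K = len(new_pos)
        self.cumulative_influx += K
        self.cohort_introduced[g] = self.cohort_introduced.get(g, 0) + K
        new_cols = np.zeros((2 * M, K), dtype=np.uint8)
        new_cols[owner, np.arange(K)] = 1
        off_haps = np.concatenate([gametes, new_cols], axis=1)
        all_pos = np.concatenate([pop.pos, new_pos])
        all_s = np.concatenate([pop.s, new_s])
        all_ids = np.concatenate(
            [pop.ids, self.id_offset + self._next_id + np.arange(K)]
        )
        all_origin = np.concatenate([pop.origin, np.full(K, g, dtype=np.int64)])
        self._next_id += K

        if M > N:
            sel_sites = np.nonzero(all_s != 0.0)[0]
            gA = off_haps[0::2][:, sel_sites].astype(np.float64)
            gB = off_haps[1::2][:, sel_sites].astype(np.float64)
            geno = gA + gB
            w = fitness(
                (geno == 1.0).astype(np.float64),
                (geno == 2.0).astype(np.float64),
                all_s[sel_sites],
                cfg.h,
            )
            order = np.lexsort((rng.random(M), -w))  # fitness desc, random ties
            survivors = np.sort(order[:N])
        else:
            survivors = np.arange(N)
        rows = np.empty(2 * N, dtype=np.int64)
        rows[0::2] = 2 * survivors
        rows[1::2] = 2 * survivors + 1
        haps = off_haps[rows]

        counts = haps.sum(axis=0, dtype=np.int64)
        fixed = counts == 2 * N
        lost = counts == 0
        n_fixed = int(fixed.sum())
        n_lost = int(lost.sum())
        self.cumulative_fixed += n_fixed
        self.cumulative_lost += n_lost
        if n_lost:
            ages = g - all_origin[lost]
            young = ages <= self.loss_window
            if young.any():
                for og, cnt in zip(
                    *np.unique(all_origin[lost][young], return_counts=True)
                ):
                    self.cohort_lost_within[int(og)] = (
                        self.cohort_lost_within.get(int(og), 0) + int(cnt)
                    )
        if cfg.track_registry and (n_fixed or n_lost):
            gone = fixed | lost
            self._registry_rows.append(
                pd.DataFrame(
                    {
                        "id": all_ids[gone],
                        "position": all_pos[gone],
                        "s": all_s[gone],
                        "origin": all_origin[gone],
                        "count": np.where(fixed[gone], 2 * N, 0),
                        "fate": np.where(fixed[gone], "fixed", "lost"),
                        "fate_generation": g,
                    }
                )
            )
        if n_fixed:
            for i in np.nonzero(fixed)[0]:
                self.fixed_background[int(all_ids[i])] = (
                    float(all_pos[i]),
                    float(all_s[i]),
                    int(all_origin[i]),
                )
        # keep columns sorted by position (gamete construction relies on it)
        keep_idx = np.nonzero(~(fixed | lost))[0]
        keep_idx = keep_idx[np.argsort(all_pos[keep_idx], kind="stable")]
        pop.haps = haps[:, keep_idx]
        pop.pos = all_pos[keep_idx]
        pop.s = all_s[keep_idx]
        pop.ids = all_ids[keep_idx]
        pop.origin = all_origin[keep_idx]

        if pop.n_sites > cfg.max_segregating:
            raise RuntimeError(
                f"segregating-site cap exceeded: {pop.n_sites} > "
                f"{cfg.max_segregating}; reduce N, mu, or generations"
            )

        counts_now = counts[keep_idx]
        f = counts_now / (2 * N)
        frequent = int(np.sum(np.minimum(f, 1 - f) > 0.25))
        self._gen_rows.append(
            (g, K, n_fixed, n_lost, pop.n_sites, frequent)
        )

    # -- whole runs -----------------------------------------------------

    def run(self, generations: Optional[int] = None) -> SimStats:
        total = (
            self.cfg.burn_in + self.cfg.generations
            if generations is None
            else generations
        )
        for _ in range(total):
            self.step()
        return self.stats()

    def stats(self) -> SimStats:
        rows = [r for r in self._gen_rows if r[0] > self.cfg.burn_in]
        arr = np.array(rows, dtype=np.int64).reshape(len(rows), 6)
        counts = self.pop.haps.sum(axis=0, dtype=np.int64)
        sfs = np.bincount(counts, minlength=2 * self.cfg.N + 1)
        return SimStats(
            generation=arr[:, 0],
            influx=arr[:, 1],
            fixations=arr[:, 2],
            losses=arr[:, 3],
            segregating=arr[:, 4],
            frequent=arr[:, 5],
            cumulative_influx=self.cumulative_influx,
            cumulative_fixed=self.cumulative_fixed,
            cumulative_lost=self.cumulative_lost,
            final_segregating=self.pop.n_sites,
            cohort_introduced=dict(self.cohort_introduced),
            cohort_lost_within=dict(self.cohort_lost_within),
            loss_window=self.loss_window,
            final_sfs=sfs,
        )

    def registry(self) -> MutationRegistry:
        """Materialize the fate table (requires ``cfg.track_registry``)."""
        if not self.cfg.track_registry:
            raise ValueError("run with track_registry=True to collect fates")
        pop = self.pop
        counts = pop.haps.sum(axis=0, dtype=np.int64)
        seg = pd.DataFrame(
            {
                "id": pop.ids,
                "position": pop.pos,
                "s": pop.s,
                "origin": pop.origin,
                "count": counts,
                "fate": "segregating",
                "fate_generation": -1,
            }
        )
        frames = self._registry_rows + [seg]
        table = pd.concat(frames, ignore_index=True).set_index("id")
        return MutationRegistry(table=table)


def run(cfg: SimConfig) -> tuple[SimStats, ForwardSimulator]:
    """Run ``burn_in + generations`` steps from an empty population."""
    sim = ForwardSimulator(cfg)
    stats = sim.run()
    return stats, sim


@dataclass
class PopulationHaplotypeStats:
    """Haplotype-architecture summary of a simulated population."""

    n_frequent: int
    n_segments: int
    n_seg_with_ch: int
    n_seg_with_yinyang: int

    @property
    def pct_seg_with_ch(self) -> float:
        return 100.0 * self.n_seg_with_ch / self.n_segments if self.n_segments else 0.0

    @property
    def pct_seg_with_yinyang(self) -> float:
        return (
            100.0 * self.n_seg_with_yinyang / self.n_segments
            if self.n_segments
            else 0.0
        )


def analyze_population(
    sim: ForwardSimulator,
    class_cfg: Optional[AnalysisConfig] = None,
) -> PopulationHaplotypeStats:
    """Classify a simulated population's frequent-SNP haplotype blocks.

    Segregating frequent mutations (MAF > threshold) are taken in
    positional order and cut into consecutive blocks of k; each block's 2N
    haplotype strings are grouped and screened for common haplotypes
    (frequency threshold, default 5%) and Yin/Yang pairs.  All simulated
    alleles are derived by construction, so every position has status R.
    """
    if class_cfg is None:
        class_cfg = AnalysisConfig(min_count=None, min_freq=0.05)
    pop = sim.pop
    n_hap = 2 * sim.cfg.N
    counts = pop.haps.sum(axis=0, dtype=np.int64)
    f = counts / n_hap
    freq_cols = np.nonzero(np.minimum(f, 1 - f) > class_cfg.maf_threshold)[0]
    freq_cols = freq_cols[np.argsort(pop.pos[freq_cols], kind="stable")]
    k = class_cfg.k
    n_segments = len(freq_cols) // k
    n_ch_seg = 0
    n_yy_seg = 0
    for b in range(n_segments):
        cols = freq_cols[b * k : (b + 1) * k]
        sub = pop.haps[:, cols].astype("U1")
        haps = ["".join(row) for row in sub]
        chset = hc.group_haplotypes(haps, class_cfg.max_intra_diff)
        chs = hc.common_haplotypes(
            chset, min_count=class_cfg.min_count, min_freq=class_cfg.min_freq
        )
        if chs:
            n_ch_seg += 1
        if hc.find_yinyang(chs, class_cfg.min_diff):
            n_yy_seg += 1
    return PopulationHaplotypeStats(
        n_frequent=len(freq_cols),
        n_segments=n_segments,
        n_seg_with_ch=n_ch_seg,
        n_seg_with_yinyang=n_yy_seg,
    )


@dataclass
class AdmixtureResult:
    """Admixed vs panmictic-control comparison."""

    admixed: PopulationHaplotypeStats
    control: PopulationHaplotypeStats
    n_private_fixed: tuple[int, int]
    t_split: int


def _merge_populations(
    sim1: ForwardSimulator,
    sim2: ForwardSimulator,
    mix: float,
    N: int,
    rng: np.random.Generator,
    founder_fixed: set[int],
) -> tuple[ForwardSimulator, tuple[int, int]]:
    """Merge two diverged lineages into one population of size N.

    Mutations that fixed post-split in exactly one lineage are reinstated
    as segregating columns (they are frequency-``mix`` variants of the
    merged gene pool); mutations fixed in both lineages stay background.
    """
    n1 = int(round(mix * N))
    n2 = N - n1
    take1 = rng.choice(sim1.cfg.N, n1, replace=False)
    take2 = rng.choice(sim2.cfg.N, n2, replace=False)

    fixed1 = {k: v for k, v in sim1.fixed_background.items() if k not in founder_fixed}
    fixed2 = {k: v for k, v in sim2.fixed_background.items() if k not in founder_fixed}
    both = set(fixed1) & set(fixed2)
    priv1 = {k: v for k, v in fixed1.items() if k not in both}
    priv2 = {k: v for k, v in fixed2.items() if k not in both}

    site_info: dict[int, tuple[float, float, int]] = {}
    for sim in (sim1, sim2):
        for i, mid in enumerate(sim.pop.ids):
            site_info[int(mid)] = (
                float(sim.pop.pos[i]),
                float(sim.pop.s[i]),
                int(sim.pop.origin[i]),
            )
    site_info.update(priv1)
    site_info.update(priv2)

    ids_sorted = sorted(site_info, key=lambda m: site_info[m][0])
    col_of = {m: j for j, m in enumerate(ids_sorted)}
    S = len(ids_sorted)
    haps = np.zeros((2 * N, S), dtype=np.uint8)

    def fill(sim: ForwardSimulator, take: np.ndarray, row0: int, priv_fixed: dict):
        rows = np.empty(2 * len(take), dtype=np.int64)
        rows[0::2] = 2 * take
        rows[1::2] = 2 * take + 1
        sub = sim.pop.haps[rows]
        for i, mid in enumerate(sim.pop.ids):
            haps[row0 : row0 + 2 * len(take), col_of[int(mid)]] = sub[:, i]
        for mid in priv_fixed:
            haps[row0 : row0 + 2 * len(take), col_of[mid]] = 1

    fill(sim1, take1, 0, priv1)
    fill(sim2, take2, 2 * n1, priv2)

    from dataclasses import replace

    merged = ForwardSimulator(replace(sim1.cfg, N=N), rng=rng)
    merged.pop.haps = haps
    merged.pop.pos = np.array([site_info[m][0] for m in ids_sorted])
    merged.pop.s = np.array([site_info[m][1] for m in ids_sorted])
    merged.pop.ids = np.array(ids_sorted, dtype=np.int64)
    merged.pop.origin = np.array([site_info[m][2] for m in ids_sorted])
    merged.fixed_background = {
        k: v
        for k, v in sim1.fixed_background.items()
        if k in founder_fixed or k in both
    }
    return merged, (len(priv1), len(priv2))


def admixture_experiment(
    cfg: SimConfig,
    t_split: int,
    mix: float = 0.5,
    class_cfg: Optional[AnalysisConfig] = None,
) -> AdmixtureResult:
    """Two-lineage split/merge experiment against a panmictic control.

    A founder population is evolved ``cfg.burn_in`` generations, then
    duplicated; the two copies evolve independently for ``t_split``
    generations and are merged at proportions (mix, 1-mix) into a single
    population of size N, analyzed immediately.  The control is the same
    founder evolved panmictically for the same ``t_split`` additional
    generations.
    """
    if t_split < 0:
        raise ValueError("t_split must be >= 0")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(5)
    from dataclasses import replace

    founder = ForwardSimulator(cfg, rng=np.random.default_rng(seeds[0]))
    founder.run(cfg.burn_in)
    founder_fixed = set(founder.fixed_background)

    def branch(seed_seq, id_offset) -> ForwardSimulator:
        sim = ForwardSimulator(cfg, rng=np.random.default_rng(seed_seq))
        sim.pop = founder.pop.copy()
        sim.generation = founder.generation
        sim._next_id = founder._next_id
        sim.id_offset = id_offset
        sim.fixed_background = dict(founder.fixed_background)
        sim.run(t_split)
        return sim

    lin1 = branch(seeds[1], 0)
    lin2 = branch(seeds[2], _LINEAGE_ID_STRIDE)
    control = branch(seeds[3], 2 * _LINEAGE_ID_STRIDE)

    merged, n_private = _merge_populations(
        lin1, lin2, mix, cfg.N, np.random.default_rng(seeds[4]), founder_fixed
    )
    return AdmixtureResult(
        admixed=analyze_population(merged, class_cfg),
        control=analyze_population(control, class_cfg),
        n_private_fixed=n_private,
        t_split=t_split,
    )


def sweep_population_size(
    sizes: Sequence[int],
    base_cfg: SimConfig,
    generations: int,
    class_cfg: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Evolve populations of different sizes for a common generation budget
    and summarize frequent-SNP counts and CH / Yin-Yang segment abundance."""
    from dataclasses import replace

    ss = np.random.SeedSequence(base_cfg.seed)
    seeds = ss.spawn(len(sizes))
    rows = []
    for N, seed_seq in zip(sizes, seeds):
        cfg = replace(base_cfg, N=int(N))
        sim = ForwardSimulator(cfg, rng=np.random.default_rng(seed_seq))
        sim.run(generations)
        pstats = analyze_population(sim, class_cfg)
        rows.append(
            {
                "N": int(N),
                "n_frequent": pstats.n_frequent,
                "n_segments": pstats.n_segments,
                "pct_seg_with_ch": pstats.pct_seg_with_ch,
                "pct_seg_with_yinyang": pstats.pct_seg_with_yinyang,
            }
        )
    return pd.DataFrame(rows)
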