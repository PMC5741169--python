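import dataclasses

import numpy as np
import pytest

import haplomosaic as hm
from haplomosaic.config import AnalysisConfig
from haplomosaic.forward_sim import (
    ForwardSimulator,
    SimConfig,
    individual_fitness,
    make_gamete,
)


def _neutral(N=20, mu=1.0, r=1, generations=50, **kw) -> SimConfig:
    return SimConfig(N=N, mu=mu, r=r, generations=generations, **kw).neutral()


class TestConfigValidation:
    def test_odd_population_size_rejected(self):
        with pytest.raises(ValueError, match="even"):
            SimConfig(N=101)

    def test_effect_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(p_del=0.5, p_ben=0.5, p_neu=0.5)

    def test_alpha_below_replacement_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(alpha=1)


class TestMakeGamete:
    def test_no_recombination_no_mutation_copies_a_parent(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig(N=2, r=0, mu=0.0).neutral()
        parent = np.array([[0, 1, 0, 1], [1, 1, 0, 0]], dtype=np.uint8)
        pos = np.array([0.1, 0.3, 0.5, 0.7])
        for _ in range(20):
            alleles, new_pos, _ = make_gamete(parent, pos, cfg, rng)
            assert len(new_pos) == 0
            assert (alleles == parent[0]).all() or (alleles == parent[1]).all()

    def test_new_mutation_count_is_poisson_mu(self):
        rng = np.random.default_rng(1)
        cfg = SimConfig(N=2, r=0, mu=5.0).neutral()
        parent = np.zeros((2, 0), dtype=np.uint8)
        pos = np.zeros(0)
        counts = [
            len(make_gamete(parent, pos, cfg, rng)[1]) for _ in range(4000)
        ]
        assert np.mean(counts) == pytest.approx(5.0, abs=0.15)
        assert np.var(counts) == pytest.approx(5.0, rel=0.15)

    def test_crossover_respects_position_order(self):
        rng = np.random.default_rng(2)
        cfg = SimConfig(N=2, r=1, mu=0.0).neutral()
        parent = np.array([[0] * 6, [1] * 6], dtype=np.uint8)
        pos = np.linspace(0.05, 0.95, 6)
        for _ in range(50):
            alleles, _, _ = make_gamete(parent, pos, cfg, rng)
            # exactly one crossover: at most one switch along the gamete
            switches = int(np.sum(alleles[1:] != alleles[:-1]))
            assert switches <= 1


class TestFitness:
    def test_mutation_free_individual_is_one(self):
        ind = np.zeros((2, 3), dtype=np.uint8)
        assert individual_fitness(ind, np.array([0.01, 0.0, 0.5]), 0.5) == 1.0

    def test_single_het_codominant(self):
        ind = np.array([[1], [0]], dtype=np.uint8)
        w = individual_fitness(ind, np.array([0.01]), 0.5)
        assert w == pytest.approx(0.995)

    def test_homozygote_full_effect_and_lethal_floor(self):
        ind = np.array([[1], [1]], dtype=np.uint8)
        assert individual_fitness(ind, np.array([0.01]), 0.5) == pytest.approx(0.99)
        assert individual_fitness(ind, np.array([1.0]), 0.5) == 0.0

    def test_log_additivity_matches_direct_product(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(-0.01, 0.02, 30)
        g = rng.integers(0, 2, (2, 30)).astype(np.uint8)
        w = individual_fitness(g, s, 0.5)
        direct = 1.0
        for j in range(30):
            n = int(g[0, j]) + int(g[1, j])
            if n == 1:
                direct *= 1 - 0.5 * s[j]
            elif n == 2:
                direct *= 1 - s[j]
        assert w == pytest.approx(direct, rel=1e-10)


class TestNextGeneration:
    def test_population_size_conserved(self):
        sim = ForwardSimulator(_neutral(N=20, generations=0))
        for _ in range(100):
            sim.step()
            assert sim.pop.haps.shape[0] == 40

    def test_alpha_two_means_everyone_survives(self):
        cfg = _neutral(N=10, mu=0.0, r=0)
        sim = ForwardSimulator(cfg)
        sim.step()
        assert sim.cumulative_lost == 0 and sim.cumulative_fixed == 0

    def test_lethal_homozygotes_are_purged_under_selection(self):
        # plant a lethal recessive at 50% frequency; with alpha=10 no
        # homozygous carrier can outrank the abundant mutation-free peers
        cfg = SimConfig(N=20, r=0, mu=0.0, alpha=10, generations=0,
                        p_del=1.0, p_ben=0.0, p_neu=0.0)
        sim = ForwardSimulator(cfg)
        sim.pop.haps = np.tile(
            np.array([[1], [0]], dtype=np.uint8), (20, 1)
        )
        sim.pop.pos = np.array([0.5])
        sim.pop.s = np.array([1.0])
        sim.pop.ids = np.array([0])
        sim.pop.origin = np.array([0])
        for _ in range(5):
            sim.step()
            if sim.pop.n_sites == 0:
                break
            geno = sim.pop.haps[0::2, 0] + sim.pop.haps[1::2, 0]
            assert not (geno == 2).any()

    def test_influx_averages_2N_mu(self):
        cfg = _neutral(N=50, mu=2.0, r=0, generations=0)
        sim = ForwardSimulator(cfg)
        for _ in range(200):
            sim.step()
        per_gen = sim.cumulative_influx / 200
        assert per_gen == pytest.approx(2 * 50 * 2.0, rel=0.05)


class TestRun:
    def test_zero_generations_no_fixations(self):
        stats, _ = hm.run(_neutral(generations=0))
        assert stats.cumulative_fixed == 0
        assert len(stats.generation) == 0

    def test_conservation_identity_every_generation(self):
        cfg = _neutral(N=20, mu=2.0, generations=150)
        stats, sim = hm.run(cfg)
        assert (
            stats.cumulative_influx
            == stats.cumulative_fixed + stats.cumulative_lost
            + stats.final_segregating
        )
        # per-generation bookkeeping: starting from an empty population,
        # seg[t] = seg[t-1] + influx[t] - fixations[t] - losses[t]
        assert stats.segregating[0] == (
            stats.influx[0] - stats.fixations[0] - stats.losses[0]
        )
        assert np.array_equal(
            np.diff(stats.segregating),
            (stats.influx - stats.fixations - stats.losses)[1:],
        )

    def test_seed_determinism_bit_identical(self):
        cfg = _neutral(N=20, mu=2.0, generations=80, seed=123)
        s1, _ = hm.run(cfg)
        s2, _ = hm.run(cfg)
        for field in ("influx", "fixations", "losses", "segregating", "frequent"):
            assert np.array_equal(getattr(s1, field), getattr(s2, field))
        s3, _ = hm.run(dataclasses.replace(cfg, seed=124))
        assert not all(
            np.array_equal(getattr(s1, f), getattr(s3, f))
            for f in ("influx", "fixations", "losses", "segregating")
        )

    def test_registry_fates_partition_influx(self):
        cfg = _neutral(N=20, mu=1.0, generations=100, track_registry=True)
        stats, sim = hm.run(cfg)
        reg = sim.registry()
        assert len(reg.table) == stats.cumulative_influx
        fates = reg.table["fate"].value_counts()
        assert fates.get("fixed", 0) == stats.cumulative_fixed
        assert fates.get("lost", 0) == stats.cumulative_lost
        assert fates.get("segregating", 0) == stats.final_segregating

    def test_segregating_cap_raises_clear_error(self):
        cfg = _neutral(N=20, mu=5.0, generations=50)
        cfg = dataclasses.replace(cfg, max_segregating=10)
        with pytest.raises(RuntimeError, match="cap"):
            hm.run(cfg)

    def test_neutral_sfs_is_dominated_by_rare_alleles(self):
        cfg = _neutral(N=50, mu=2.0, r=1, generations=600)
        stats, _ = hm.run(cfg)
        sfs = stats.final_sfs
        # singletons outnumber any higher copy class; tail is depleted
        assert sfs[1] == sfs[1:].max()
        assert sfs[1] > 5 * sfs[1 + len(sfs) // 2 : -1].max()


class TestAnalyzePopulation:
    def test_monomorphic_population_has_no_segments(self):
        sim = ForwardSimulator(_neutral(N=20, mu=0.0, generations=0))
        sim.run(10)
        pstats = hm.analyze_population(sim)
        assert pstats.n_frequent == 0 and pstats.n_segments == 0

    def test_blocks_of_k_frequent_sites(self):
        cfg = _neutral(N=30, mu=3.0, r=1, generations=400, seed=5)
        _, sim = hm.run(cfg)
        class_cfg = AnalysisConfig(min_count=None, min_freq=0.05, k=10)
        pstats = hm.analyze_population(sim, class_cfg)
        assert pstats.n_segments == pstats.n_frequent // 10
        assert 0 <= pstats.n_seg_with_yinyang <= pstats.n_seg_with_ch


class TestAdmixture:
    def test_merge_reinstates_private_fixed_differences(self):
        cfg = _neutral(N=20, mu=1.0, r=1, seed=9)
        cfg = dataclasses.replace(cfg, burn_in=100)
        res = hm.admixture_experiment(cfg, t_split=150)
        n1, n2 = res.n_private_fixed
        assert n1 > 0 and n2 > 0
        # every private fixed difference is a ~50% variant of the merged
        # pool, so the frequent-SNP count is at least their total
        assert res.admixed.n_frequent >= n1 + n2

    def test_zero_split_time_is_a_null_experiment(self):
        cfg = _neutral(N=20, mu=1.0, r=1, seed=10)
        cfg = dataclasses.replace(cfg, burn_in=60)
        res = hm.admixture_experiment(cfg, t_split=0)
        assert res.n_private_fixed == (0, 0)
        # both arms are the same founder population: counts are comparable
        assert res.admixed.n_frequent <= 3 * max(res.control.n_frequent, 10)
        assert res.control.n_frequent <= 3 * max(res.admixed.n_frequent, 10)

    def test_negative_split_time_rejected(self):
        with pytest.raises(ValueError):
            hm.admixture_experiment(_neutral(), t_split=-1)
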