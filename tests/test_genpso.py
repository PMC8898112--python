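import numpy as np
import pytest

from genpsowvq.genpso import (Chromosome, GenPSOConfig, ga_phase,
                              genpso_optimize, init_population, mutate,
                              node_crossover, pso_phase, tournament_select)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def rastrigin(x):
    x = np.asarray(x)
    return float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


class TestInitPopulation:
    def test_deterministic(self):
        a = init_population(10, 7, seed=3)
        b = init_population(10, 7, seed=3)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.genome, cb.genome)

    def test_sizes(self):
        pop = init_population(50, 10, seed=0)
        assert len(pop) == 50
        assert all(c.genome.shape == (10,) for c in pop)

    def test_mean_near_zero(self):
        pop = init_population(100, 100, seed=1)
        genes = np.concatenate([c.genome for c in pop])
        assert abs(genes.mean()) < 0.01

    def test_invalid_sizes_raise(self):
        with pytest.raises(ValueError):
            init_population(2, 5, seed=0)
        with pytest.raises(ValueError):
            init_population(10, 0, seed=0)


class TestNodeCrossover:
    NODES = [np.array([0, 1, 2]), np.array([3, 4]), np.array([5, 6, 7])]

    def test_identical_parents_give_identical_offspring(self):
        g = np.arange(8.0)
        o1, o2 = node_crossover(Chromosome(g.copy()), Chromosome(g.copy()),
                                self.NODES, np.random.default_rng(0))
        np.testing.assert_array_equal(o1.genome, g)
        np.testing.assert_array_equal(o2.genome, g)

    def test_offspring_differ_exactly_on_chosen_node(self):
        a = Chromosome(np.zeros(8))
        b = Chromosome(np.ones(8))
        rng = np.random.default_rng(5)
        chosen = np.random.default_rng(5).integers(len(self.NODES))
        o1, o2 = node_crossover(a, b, self.NODES, rng)
        idx = self.NODES[chosen]
        mask = np.zeros(8, dtype=bool)
        mask[idx] = True
        np.testing.assert_array_equal(o1.genome[mask], b.genome[idx])
        np.testing.assert_array_equal(o1.genome[~mask], a.genome[~mask])
        np.testing.assert_array_equal(o2.genome[mask], a.genome[idx])
        np.testing.assert_array_equal(o2.genome[~mask], b.genome[~mask])

    def test_slice_multiset_is_conserved(self, rng):
        a = Chromosome(rng.normal(size=8))
        b = Chromosome(rng.normal(size=8))
        o1, o2 = node_crossover(a, b, self.NODES, rng)
        for idx in self.NODES:
            parents = {tuple(a.genome[idx]), tuple(b.genome[idx])}
            children = {tuple(o1.genome[idx]), tuple(o2.genome[idx])}
            assert parents == children

    def test_mismatched_parents_raise(self):
        with pytest.raises(ValueError):
            node_crossover(Chromosome(np.zeros(3)), Chromosome(np.zeros(4)),
                           None, np.random.default_rng(0))


class TestMutate:
    def test_zero_scale_is_identity(self, rng):
        c = Chromosome(rng.normal(size=20))
        out = mutate(c, rate=0.5, scale=0.0, rng=rng)
        np.testing.assert_array_equal(out.genome, c.genome)

    def test_no_hits_is_identity(self):
        # tiny rate with a generator whose first draws all exceed it
        rng = np.random.default_rng(1)
        c = Chromosome(np.zeros(10))
        out = mutate(c, rate=1e-12, scale=1.0, rng=rng)
        np.testing.assert_array_equal(out.genome, c.genome)

    def test_hit_frequency(self):
        rng = np.random.default_rng(2)
        c = Chromosome(np.zeros(100_000))
        out = mutate(c, rate=0.1, scale=1.0, rng=rng)
        freq = np.mean(out.genome != 0.0)
        assert abs(freq - 0.1) < 0.01

    def test_invalid_rate_raises(self, rng):
        with pytest.raises(ValueError):
            mutate(Chromosome(np.zeros(3)), rate=0.0, scale=1.0, rng=rng)


class TestTournament:
    def _mixed(self, fitnesses):
        return [Chromosome(np.array([float(i)]), fitness=f)
                for i, f in enumerate(fitnesses)]

    def test_best_always_survives(self):
        for seed in range(50):
            mixed = self._mixed([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
            survivors = tournament_select(mixed, 0.1,
                                          np.random.default_rng(seed))
            assert any(c.fitness == 0.1 for c in survivors)

    def test_survivor_count_is_half(self):
        mixed = self._mixed(np.random.default_rng(0).random(20))
        assert len(tournament_select(mixed, 0.1, np.random.default_rng(1))) == 10

    def test_opponent_count_rounding(self):
        # 2μ = 100 → each meets round(0.1·100) = 10 opponents
        mixed = self._mixed(np.linspace(0, 1, 100))
        tournament_select(mixed, 0.1, np.random.default_rng(3))
        assert max(c.wins for c in mixed) == 10   # the best wins all ten
        assert all(c.wins <= 10 for c in mixed)

    def test_unevaluated_raises(self):
        mixed = [Chromosome(np.zeros(1)) for _ in range(4)]
        with pytest.raises(ValueError, match="evaluated"):
            tournament_select(mixed, 0.1, np.random.default_rng(0))


class TestGAPhase:
    def test_constant_objective_stops_after_exactly_window(self):
        cfg = GenPSOConfig(population_size=10, stagnation_window=5, seed=0)
        res = ga_phase(lambda g: 1.0, 3, cfg)
        assert len(res.history) == 5
        assert res.evaluations == 10 * (1 + 5)

    def test_quadratic_minimum_found(self):
        cfg = GenPSOConfig(population_size=20, ga_max_gen=200,
                           stagnation_window=50, seed=2)
        res = ga_phase(lambda g: float((g[0] - 3.0) ** 2), 1, cfg)
        assert abs(res.best.genome[0] - 3.0) < 0.1

    def test_elitist_history_is_non_increasing(self):
        cfg = GenPSOConfig(population_size=10, ga_max_gen=60,
                           stagnation_window=30, seed=3)
        res = ga_phase(sphere, 4, cfg)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))

    def test_non_finite_objective_raises(self):
        cfg = GenPSOConfig(population_size=4, seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            ga_phase(lambda g: float("nan"), 2, cfg)

    def test_population_100_variant_stagnates(self):
        # scaled-down run of the larger-population configuration
        cfg = GenPSOConfig(population_size=100, stagnation_window=10, seed=4)
        res = ga_phase(lambda g: 0.5, 2, cfg)
        assert len(res.history) == 10
        assert res.evaluations == 100 * (1 + 10)


class TestPSOPhase:
    def _seeded_pop(self, n, dim, seed, objective):
        pop = init_population(n, dim, seed)
        for c in pop:
            c.fitness = objective(c.genome)
        return pop

    def test_start_at_optimum_exits_immediately(self):
        pop = [Chromosome(np.zeros(3), fitness=0.0) for _ in range(4)]
        cfg = GenPSOConfig(population_size=4, pso_max_iter=100)
        res = pso_phase(pop, sphere, cfg)
        assert res.best_fitness == 0.0
        assert len(res.history) == 1
        assert res.evaluations == 0

    def test_gbest_trace_non_increasing(self):
        pop = self._seeded_pop(10, 4, 5, sphere)
        cfg = GenPSOConfig(population_size=10, pso_max_iter=50, pso_tol=1e-12)
        res = pso_phase(pop, sphere, cfg)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))

    def test_gbest_is_a_copy(self):
        pop = self._seeded_pop(10, 4, 6, sphere)
        cfg = GenPSOConfig(population_size=10, pso_max_iter=30, pso_tol=1e-12)
        res = pso_phase(pop, sphere, cfg)
        assert sphere(res.best_position) == pytest.approx(res.best_fitness)

    def test_empty_seed_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            pso_phase([], sphere, GenPSOConfig())


class TestHybrid:
    def test_sphere_dim2(self):
        cfg = GenPSOConfig(population_size=20, ga_max_gen=100,
                           stagnation_window=50, pso_max_iter=500,
                           pso_tol=1e-7, seed=1)
        res = genpso_optimize(sphere, 2, cfg)
        assert res.best_fitness < 1e-4

    def test_hybrid_not_worse_than_ga(self):
        cfg = GenPSOConfig(population_size=20, ga_max_gen=50,
                           stagnation_window=25, pso_max_iter=100, seed=7)
        rng = np.random.default_rng(cfg.seed)
        ga = ga_phase(sphere, 3, cfg, rng)
        res = genpso_optimize(sphere, 3, cfg)
        assert res.best_fitness <= ga.best.fitness

    def test_bit_identical_traces_same_seed(self):
        cfg = GenPSOConfig(population_size=10, ga_max_gen=30,
                           stagnation_window=15, pso_max_iter=40,
                           pso_tol=1e-12, seed=9)
        r1 = genpso_optimize(rastrigin, 3, cfg)
        r2 = genpso_optimize(rastrigin, 3, cfg)
        assert r1.ga_history == r2.ga_history
        assert r1.pso_history == r2.pso_history
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        assert r1.evaluations == r2.evaluations

    def test_evaluation_budget_pinned(self):
        cfg = GenPSOConfig(population_size=10, stagnation_window=5,
                           pso_max_iter=3, seed=0)
        res = genpso_optimize(lambda g: 2.0, 4, cfg)
        # GA: 10 initial + 10 per each of 5 flat generations; PSO: 10×3
        assert res.evaluations == 10 * (1 + 5) + 10 * 3

    def test_rastrigin_beats_equal_budget_random_search(self):
        cfg = GenPSOConfig(population_size=20, ga_max_gen=100,
                           stagnation_window=101, pso_max_iter=149,
                           pso_tol=1e-15, seed=11)
        res = genpso_optimize(rastrigin, 2, cfg)
        assert res.evaluations == 5000
        rng = np.random.default_rng(11)
        random_best = min(rastrigin(rng.uniform(-0.5, 0.5, 2))
                          for _ in range(5000))
        assert res.best_fitness <= random_best

    def test_trace_csv_round_trip(self, tmp_path):
        cfg = GenPSOConfig(population_size=10, ga_max_gen=10,
                           stagnation_window=5, pso_max_iter=5, seed=0)
        res = genpso_optimize(sphere, 2, cfg)
        path = tmp_path / "trace.csv"
        res.write_trace(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "phase,step,best_fitness"
        assert len(lines) == 1 + len(res.ga_history) + len(res.pso_history)
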