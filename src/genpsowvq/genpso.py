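"""Hybrid GA → PSO derivative-free optimizer (GenPSO).

The optimizer runs in two phases over a fixed-length real genome (network
weights or stacked codewords):

1. **GA phase** — a (μ + μ) evolutionary loop.  Each generation draws μ
   offspring by node-level crossover of uniformly chosen parent pairs
   followed by per-gene gaussian mutation, evaluates them, randomly mixes
   parents and offspring, and keeps the μ individuals that score the most
   wins in a tournament against 10% of the mixed population.  The phase
   stops when the best fitness has stagnated — its range over the last N
   generations falls below a tolerance (default 1e-5 over N = 50) — or at
   a hard generation cap.

2. **PSO phase** — the GA's final population becomes the particle swarm:
   positions are the surviving genomes, velocities start at zero, and the
   standard inertia-weight velocity/position update with per-coordinate
   uniform random factors refines the solution, tracking each particle's
   personal best (pbest) and the swarm's global best (gbest).

*Node crossover* swaps the complete incoming-weight slice (weights plus
bias) of one randomly chosen node between the two parents, so recombination
exchanges functional units rather than arbitrary gene spans.  When no node
structure is supplied every gene is its own node.

A run is a pure function of (objective, config): all randomness flows from
one seeded generator, total objective evaluations are counted, and the
best-fitness trace per generation/iteration is returned for plotting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Chromosome",
    "Particle",
    "GenPSOConfig",
    "GAResult",
    "PSOResult",
    "OptimizeResult",
    "init_population",
    "node_crossover",
    "mutate",
    "tournament_select",
    "ga_phase",
    "pso_phase",
    "genpso_optimize",
]


@dataclass
class Chromosome:
    """One GA candidate: a flat genome with its fitness and tournament wins."""

    genome: np.ndarray
    fitness: float | None = None
    wins: int = 0


@dataclass
class Particle:
    """One PSO particle with its personal-best memory."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class GenPSOConfig:
    """Tunable parameters of the hybrid optimizer.

    Defaults follow the reported experimental settings where stated
    (population 50, stagnation window 50 at tolerance 1e-5) and standard
    constriction-equivalent PSO coefficients (w = 0.729,
    c1 = c2 = 1.49445) elsewhere.
    """

    population_size: int = 50
    stagnation_window: int = 50
    stagnation_tol: float = 1e-5
    stagnation_mode: str = "range"  # "range" | "delta" over the window
    mutation_rate: float = 0.05
    mutation_scale: float = 0.1
    ga_max_gen: int = 500
    elitism: bool = True
    opponent_fraction: float = 0.1
    pso_inertia: float = 0.729
    pso_c1: float = 1.49445
    pso_c2: float = 1.49445
    pso_max_iter: int = 500
    pso_tol: float = 1e-5
    velocity_clamp: float = 1.0
    init_lo: float = -0.5
    init_hi: float = 0.5
    seed: int = 0
    node_shape: list[np.ndarray] | None = None

    def validate(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 4")
        if not (0.0 < self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in (0, 1]")
        for name in ("stagnation_tol", "pso_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stagnation_mode not in ("range", "delta"):
            raise ValueError("stagnation_mode must be 'range' or 'delta'")


@dataclass
class GAResult:
    population: list[Chromosome]
    best: Chromosome
    history: list[float]
    evaluations: int


@dataclass
class PSOResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    evaluations: int


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    ga_history: list[float] = field(default_factory=list)
    pso_history: list[float] = field(default_factory=list)
    evaluations: int = 0

    def write_trace(self, path) -> None:
        """Dump the best-fitness trace as CSV (phase, step, best_fitness)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["phase", "step", "best_fitness"])
            for i, v in enumerate(self.ga_history):
                w.writerow(["ga", i, repr(v)])
            for i, v in enumerate(self.pso_history):
                w.writerow(["pso", i, repr(v)])


class _CountedObjective:
    """Wraps the user objective: counts calls and rejects non-finite values."""

    def __init__(self, fn):
        self.fn = fn
        self.calls = 0

    def __call__(self, genome: np.ndarray) -> float:
        self.calls += 1
        value = float(self.fn(genome))
        if not np.isfinite(value):
            raise ValueError(
                f"objective returned a non-finite value ({value}) "
                f"at evaluation {self.calls}"
            )
        return value


def init_population(mu: int, dim: int, seed, lo: float = -0.5,
                    hi: float = 0.5) -> list[Chromosome]:
    """μ chromosomes with genes i.i.d. uniform on [lo, hi].

    ``seed`` may be an integer or an existing ``numpy.random.Generator``.
    """
    if mu < 4:
        raise ValueError("population size must be >= 4")
    if dim < 1:
        raise ValueError("genome dimension must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return [Chromosome(genome=rng.uniform(lo, hi, size=dim))
            for _ in range(mu)]


def _gene_nodes(dim: int) -> list[np.ndarray]:
    return [np.asarray([i], dtype=np.intp) for i in range(dim)]


def node_crossover(a: Chromosome, b: Chromosome,
                   node_shape: list[np.ndarray] | None,
                   rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """Swap the incoming-weight slice of one random node between parents.

    The node is drawn uniformly over all nodes in ``node_shape`` (hidden
    and output nodes alike for a network genome); offspring A is a copy of
    parent ``a`` with that node's slice taken from ``b`` and vice versa.
    """
    if a.genome.shape != b.genome.shape:
        raise ValueError("parent genomes must have equal length")
    nodes = node_shape if node_shape is not None else _gene_nodes(a.genome.size)
    idx = nodes[int(rng.integers(len(nodes)))]
    if np.max(idx) >= a.genome.size:
        raise ValueError("node_shape indexes beyond the genome")
    ga, gb = a.genome.copy(), b.genome.copy()
    ga[idx], gb[idx] = b.genome[idx], a.genome[idx]
    return Chromosome(genome=ga), Chromosome(genome=gb)


def mutate(c: Chromosome, rate: float, scale: float,
           rng: np.random.Generator) -> Chromosome:
    """Per-gene gaussian mutation: each gene is hit with probability
    ``rate`` and perturbed by N(0, scale²)."""
    if not (0.0 < rate <= 1.0):
        raise ValueError("mutation rate must be in (0, 1]")
    g = c.genome.copy()
    mask = rng.random(g.size) < rate
    noise = rng.normal(0.0, scale, size=g.size)
    g[mask] += noise[mask]
    return Chromosome(genome=g)


def tournament_select(mixed: list[Chromosome],
                      opponent_fraction: float = 0.1,
                      rng: np.random.Generator | None = None) -> list[Chromosome]:
    """Keep the better half of a mixed parent+offspring population.

    Every chromosome meets ``round(opponent_fraction·|mixed|)`` distinct
    random opponents (never itself) and scores a win for each opponent with
    strictly worse (higher) fitness.  The half with the most wins survives;
    ties break by better fitness, then by stable input order.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = len(mixed)
    if n < 2 or n % 2:
        raise ValueError("mixed population size must be even and >= 2")
    for c in mixed:
        if c.fitness is None:
            raise ValueError("all chromosomes must be evaluated before selection")
    k = max(1, round(opponent_fraction * n))
    for i, c in enumerate(mixed):
        others = np.delete(np.arange(n), i)
        opponents = rng.choice(others, size=min(k, n - 1), replace=False)
        c.wins = int(sum(mixed[j].fitness > c.fitness for j in opponents))
    order = sorted(range(n),
                   key=lambda i: (-mixed[i].wins, mixed[i].fitness, i))
    return [mixed[i] for i in order[: n // 2]]


def _evaluate(pop: list[Chromosome], objective) -> None:
    for c in pop:
        if c.fitness is None:
            c.fitness = objective(c.genome)


def _stagnated(history: list[float], cfg: GenPSOConfig) -> bool:
    n = cfg.stagnation_window
    if len(history) < n:
        return False
    window = history[-n:]
    if cfg.stagnation_mode == "range":
        return max(window) - min(window) < cfg.stagnation_tol
    return all(abs(window[i] - window[i + 1]) < cfg.stagnation_tol
               for i in range(n - 1))


def ga_phase(objective, dim: int, config: GenPSOConfig,
             rng: np.random.Generator | None = None,
             init: list[np.ndarray] | None = None) -> GAResult:
    """Run the GA phase; returns the final population and fitness trace.

    ``init`` optionally supplies the initial genomes (e.g. data-seeded
    codebooks) in place of the uniform random population.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    obj = objective if isinstance(objective, _CountedObjective) \
        else _CountedObjective(objective)
    mu = config.population_size

    if init is not None:
        if len(init) != mu:
            raise ValueError("init population size must equal population_size")
        parents = [Chromosome(genome=np.asarray(g, dtype=np.float64).copy())
                   for g in init]
    else:
        parents = init_population(mu, dim, rng, config.init_lo, config.init_hi)
    _evaluate(parents, obj)

    incumbent = min(parents, key=lambda c: c.fitness)
    incumbent = Chromosome(genome=incumbent.genome.copy(),
                           fitness=incumbent.fitness)
    history: list[float] = []

    for _ in range(config.ga_max_gen):
        offspring: list[Chromosome] = []
        while len(offspring) < mu:
            i = int(rng.integers(mu))
            j = int(rng.integers(mu - 1))
            j = j + 1 if j >= i else j  # uniform pair without self-pairing
            o1, o2 = node_crossover(parents[i], parents[j],
                                    config.node_shape, rng)
            offspring.append(mutate(o1, config.mutation_rate,
                                    config.mutation_scale, rng))
            if len(offspring) < mu:
                offspring.append(mutate(o2, config.mutation_rate,
                                        config.mutation_scale, rng))
        _evaluate(offspring, obj)

        mixed = parents + offspring
        mixed = [mixed[i] for i in rng.permutation(2 * mu)]
        parents = tournament_select(mixed, config.opponent_fraction, rng)

        gen_best = min(parents, key=lambda c: c.fitness)
        if gen_best.fitness < incumbent.fitness:
            incumbent = Chromosome(genome=gen_best.genome.copy(),
                                   fitness=gen_best.fitness)
        elif config.elitism and incumbent.fitness < gen_best.fitness:
            worst = max(range(len(parents)),
                        key=lambda i: parents[i].fitness)
            parents[worst] = Chromosome(genome=incumbent.genome.copy(),
                                        fitness=incumbent.fitness)
        best_now = incumbent.fitness if config.elitism \
            else min(c.fitness for c in parents)
        history.append(best_now)
        if _stagnated(history, config):
            break

    best = incumbent if config.elitism else \
        min(parents, key=lambda c: c.fitness)
    return GAResult(population=parents, best=Chromosome(
        genome=best.genome.copy(), fitness=best.fitness),
        history=history, evaluations=obj.calls)


def pso_phase(seed_population: list[Chromosome], objective,
              config: GenPSOConfig,
              rng: np.random.Generator | None = None) -> PSOResult:
    """Refine the GA's final population with inertia-weight PSO.

    Particles start at the GA genomes with zero velocity; pbest/gbest are
    updated on strict improvement and gbest is stored as a copy so later
    particle movement cannot corrupt it.  Stops when gbest falls below
    ``pso_tol`` (checked before each iteration) or after ``pso_max_iter``.
    """
    config.validate()
    if not seed_population:
        raise ValueError("PSO requires a non-empty seed population")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    obj = objective if isinstance(objective, _CountedObjective) \
        else _CountedObjective(objective)

    for c in seed_population:
        if c.fitness is None:
            c.fitness = obj(c.genome)

    x = np.stack([c.genome for c in seed_population]).astype(np.float64)
    f = np.asarray([c.fitness for c in seed_population], dtype=np.float64)
    n, dim = x.shape
    v = np.zeros_like(x)
    pbest_x = x.copy()
    pbest_f = f.copy()
    g = int(np.argmin(pbest_f))
    gbest_x = pbest_x[g].copy()
    gbest_f = float(pbest_f[g])
    history = [gbest_f]

    for _ in range(config.pso_max_iter):
        if gbest_f < config.pso_tol:
            break
        r1 = rng.random((n, dim))
        r2 = rng.random((n, dim))
        v = (config.pso_inertia * v
             + config.pso_c1 * r1 * (pbest_x - x)
             + config.pso_c2 * r2 * (gbest_x - x))
        np.clip(v, -config.velocity_clamp, config.velocity_clamp, out=v)
        x = x + v
        f = np.asarray([obj(x[i]) for i in range(n)])
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        history.append(gbest_f)

    return PSOResult(best_position=gbest_x, best_fitness=gbest_f,
                     history=history, evaluations=obj.calls)


def genpso_optimize(objective, dim: int,
                    config: GenPSOConfig | None = None,
                    init: list[np.ndarray] | None = None) -> OptimizeResult:
    """Full hybrid run: GA phase, then PSO seeded with the GA population.

    Returns the better of the two phases' bests, with the per-phase
    best-fitness traces and the total objective evaluation count.
    """
    if config is None:
        config = GenPSOConfig()
    config.validate()
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    obj = _CountedObjective(objective)
    ga = ga_phase(obj, dim, config, rng, init=init)
    pso = pso_phase(ga.population, obj, config, rng)
    if ga.best.fitness <= pso.best_fitness:
        best_x, best_f = ga.best.genome, ga.best.fitness
    else:
        best_x, best_f = pso.best_position, pso.best_fitness
    return OptimizeResult(best_position=np.asarray(best_x, dtype=np.float64),
                          best_fitness=float(best_f),
                          ga_history=ga.history, pso_history=pso.history,
                          evaluations=obj.calls)
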