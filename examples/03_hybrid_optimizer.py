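"""Minimize test functions with the hybrid GA→PSO optimizer.

Shows the two phases at work: the GA explores until its best fitness
stagnates, then the particle swarm refines the GA's final population.
"""

import numpy as np

from genpsowvq import GenPSOConfig, genpso_optimize


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def rastrigin(x):
    x = np.asarray(x)
    return float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


for name, fn, dim in (("sphere", sphere, 5), ("rastrigin", rastrigin, 2)):
    cfg = GenPSOConfig(population_size=20, ga_max_gen=100,
                       stagnation_window=50, pso_max_iter=500,
                       pso_tol=1e-12, seed=1)
    res = genpso_optimize(fn, dim, cfg)
    print(f"{name} (dim {dim}):")
    print(f"  GA  phase: {len(res.ga_history)} generations, "
          f"best {res.ga_history[-1]:.3e}")
    print(f"  PSO phase: {len(res.pso_history) - 1} iterations, "
          f"best {res.pso_history[-1]:.3e}")
    print(f"  total objective evaluations: {res.evaluations}")

print()
print("Both functions have their global minimum at 0; the PSO phase")
print("refines whatever the GA hands over (how much depends on how")
print("converged, and hence how diverse, the GA population still is).")
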