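"""Train a vector-quantization codebook with GenPSO and sanity-check it.

Two well-separated gaussian clusters in 3-D: the optimal 2-word codebook
puts one codeword on each cluster mean. The K=1 case must collapse to the
global centroid.
"""

import numpy as np

from genpsowvq import Codebook, GenPSOConfig, build_codebook, distortion

rng = np.random.default_rng(0)
a = rng.normal(0.25, 0.03, size=(40, 3))
b = rng.normal(0.75, 0.03, size=(40, 3))
data = np.vstack([a, b])

cfg = GenPSOConfig(population_size=30, ga_max_gen=60, stagnation_window=30,
                   pso_max_iter=300, velocity_clamp=0.2, seed=1)
cb2 = build_codebook(data, K=2, config=cfg)
print("K=2 codewords:")
print(np.round(cb2.codewords, 3))
print(f"distortion: {distortion(data, cb2):.6f} "
      f"(cluster means sit near 0.25 and 0.75)")

cb1 = build_codebook(data, K=1, config=cfg)
centroid = data.mean(axis=0, keepdims=True)
print(f"\nK=1 codeword {np.round(cb1.codewords[0], 3)} vs "
      f"centroid {np.round(centroid[0], 3)}")
print(f"distortion {distortion(data, cb1):.6f} vs centroid optimum "
      f"{distortion(data, Codebook(centroid)):.6f}")
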