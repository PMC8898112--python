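"""Vector quantization of hidden-layer activation vectors.

The codec transmits, per 8×8 block, only the index of the codeword nearest
to the block's hidden code, so the rate per block is ``log2(K)`` bits for a
K-word codebook.  The codebook itself is *trained* — like the network
weights — by the hybrid GenPSO optimizer: the genome is the concatenation
of the K codewords and the objective is the mean squared distance of the
training codes to their nearest codeword (the usual VQ distortion).

The GA's initial population mixes two kinds of candidates half/half:
random K-subsets of the training vectors (so an exact cover is present
whenever K reaches the number of distinct codes) and uniform random
codebooks over the data bounding box.  Additional candidate codebooks —
for example a smaller trained codebook padded with duplicates — can be
injected explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .genpso import GenPSOConfig, genpso_optimize

__all__ = [
    "Codebook",
    "IndexStream",
    "distortion",
    "build_codebook",
    "vq_encode",
    "vq_decode",
]


@dataclass
class Codebook:
    """Ordered set of K codewords of dimension H; K must be a power of two
    so the index bit-width ``log2(K)`` is integral."""

    codewords: np.ndarray

    def __post_init__(self):
        cw = np.asarray(self.codewords, dtype=np.float64)
        if cw.ndim != 2 or cw.shape[0] < 1:
            raise ValueError("codewords must be a non-empty (K, H) array")
        if cw.shape[0] & (cw.shape[0] - 1):
            raise ValueError(f"K must be a power of two, got {cw.shape[0]}")
        self.codewords = cw

    @property
    def K(self) -> int:
        return self.codewords.shape[0]

    @property
    def dim(self) -> int:
        return self.codewords.shape[1]

    @property
    def bitwidth(self) -> int:
        return max(1, self.K.bit_length() - 1) if self.K > 1 else 1


@dataclass
class IndexStream:
    """Codeword indices for a sequence of vectors, plus the index
    bit-width used when packing them into the bitstream."""

    indices: np.ndarray
    bitwidth: int

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if idx.size and (idx.min() < 0 or idx.max() >= (1 << self.bitwidth)):
            raise ValueError("index out of range for the bit-width")
        self.indices = idx

    @property
    def bit_count(self) -> int:
        return self.indices.size * self.bitwidth


def _check_vectors(vectors, dim: int | None = None) -> np.ndarray:
    v = np.asarray(vectors, dtype=np.float64)
    if v.ndim != 2 or v.shape[0] == 0:
        raise ValueError("expected a non-empty (n, H) array of vectors")
    if dim is not None and v.shape[1] != dim:
        raise ValueError(
            f"vector dimension {v.shape[1]} does not match codebook "
            f"dimension {dim}"
        )
    return v


def distortion(vectors, codebook: Codebook) -> float:
    """Mean squared euclidean distance to the nearest codeword."""
    v = _check_vectors(vectors, codebook.dim)
    d2 = cdist(v, codebook.codewords, metric="sqeuclidean")
    return float(np.mean(d2.min(axis=1)))


def vq_encode(vectors, codebook: Codebook) -> IndexStream:
    """Nearest-codeword index per vector; ties break to the lowest index."""
    v = _check_vectors(vectors, codebook.dim)
    d2 = cdist(v, codebook.codewords, metric="sqeuclidean")
    # np.argmin returns the first (lowest) index among ties.
    return IndexStream(indices=np.argmin(d2, axis=1),
                       bitwidth=codebook.bitwidth)


def vq_decode(stream: IndexStream, codebook: Codebook) -> np.ndarray:
    """Codeword lookup: index i → codeword i."""
    idx = stream.indices
    if idx.size and idx.max() >= codebook.K:
        raise ValueError("index stream refers beyond the codebook")
    return codebook.codewords[idx].copy()


def _seed_codebooks(v: np.ndarray, K: int, mu: int,
                    rng: np.random.Generator,
                    extra: list[np.ndarray] | None) -> list[np.ndarray]:
    """Half data-subset seeds, half uniform over the data bounding box."""
    n = v.shape[0]
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    seeds: list[np.ndarray] = []
    if extra:
        seeds.extend(np.asarray(g, dtype=np.float64).ravel() for g in extra)
    n_subset = max(0, mu // 2 - len(seeds))
    for _ in range(n_subset):
        pick = rng.choice(n, size=K, replace=(n < K))
        seeds.append(v[pick].ravel())
    while len(seeds) < mu:
        seeds.append((lo + span * rng.random((K, v.shape[1]))).ravel())
    return seeds[:mu]


def build_codebook(training_vectors, K: int,
                   config: GenPSOConfig | None = None,
                   seed_codebooks: list[np.ndarray] | None = None
                   ) -> Codebook:
    """Train a K-word codebook on hidden codes by GenPSO.

    ``seed_codebooks`` optionally injects explicit candidate codebooks
    (flattened (K, H) arrays) into the GA's initial population; the
    returned codebook's distortion never exceeds the best candidate's,
    because the elitist GA keeps its incumbent.
    """
    if K < 1 or K & (K - 1):
        raise ValueError("K must be a positive power of two")
    v = _check_vectors(training_vectors)
    h = v.shape[1]
    if config is None:
        config = GenPSOConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    init = _seed_codebooks(v, K, config.population_size, rng, seed_codebooks)

    def objective(genome: np.ndarray) -> float:
        cw = genome.reshape(K, h)
        d2 = cdist(v, cw, metric="sqeuclidean")
        return float(np.mean(d2.min(axis=1)))

    # node structure: each codeword is one node, so crossover swaps whole
    # codewords between parent codebooks.
    nodes = [np.arange(i * h, (i + 1) * h, dtype=np.intp) for i in range(K)]
    cfg = replace(config, node_shape=nodes)
    result = genpso_optimize(objective, K * h, cfg, init=init)
    return Codebook(codewords=result.best_position.reshape(K, h))
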