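"""The 64-H-64 compressor network.

Each 8×8 block, flattened to a 64-vector in [0, 1], is mapped by a single
hidden layer of H logistic-sigmoid units to a code in (0, 1)^H and back to
a 64-vector in (0, 1) by the output layer.  H is the bottleneck: the code
(after vector quantization) is what travels in the bitstream, so smaller H
means stronger compression and larger H more fidelity.

An optional Elman-style context matrix feeds the previous block's hidden
state back into the current one (hidden-state feedback), giving the encoder
short-range memory along the raster scan.  With the context disabled the
network is a plain block autoencoder and every block is coded
independently.

Nothing here is trained by gradients: the whole parameter vector (in the
fixed flattening order ``w_in, b_hidden, [w_rec,] w_out, b_out``) is the
genome the GenPSO optimizer evolves against :func:`reconstruction_fitness`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelet_blocks import BlockSet

__all__ = [
    "ALLOWED_HIDDEN",
    "NetShape",
    "CompressorNet",
    "init_network",
    "forward",
    "encode_blocks",
    "decode_hidden",
    "reconstruction_fitness",
]

#: Hidden-layer widths the codec supports.
ALLOWED_HIDDEN = (2, 4, 8, 16, 32, 64)

N_INPUT = 64


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically safe logistic; output strictly inside (0, 1)
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


@dataclass(frozen=True)
class NetShape:
    """Static description of a network's parameter layout."""

    n_hidden: int
    recurrent: bool

    @property
    def n_params(self) -> int:
        h = self.n_hidden
        n = N_INPUT * h + h + h * N_INPUT + N_INPUT
        if self.recurrent:
            n += h * h
        return n

    def node_slices(self) -> list[np.ndarray]:
        """Index groups of incoming weights (and bias) per node.

        Used by the GA's node crossover: one group per hidden node (its
        column of ``w_in``, its bias and, when recurrence is on, its column
        of ``w_rec``) and one per output node (its column of ``w_out`` and
        its bias).
        """
        h = self.n_hidden
        groups: list[np.ndarray] = []
        off_w_in = 0
        off_b_h = N_INPUT * h
        off_w_rec = off_b_h + h
        off_w_out = off_w_rec + (h * h if self.recurrent else 0)
        off_b_out = off_w_out + h * N_INPUT
        for j in range(h):
            idx = [off_w_in + i * h + j for i in range(N_INPUT)]
            idx.append(off_b_h + j)
            if self.recurrent:
                idx.extend(off_w_rec + i * h + j for i in range(h))
            groups.append(np.asarray(idx, dtype=np.intp))
        for k in range(N_INPUT):
            idx = [off_w_out + j * N_INPUT + k for j in range(h)]
            idx.append(off_b_out + k)
            groups.append(np.asarray(idx, dtype=np.intp))
        return groups


@dataclass
class CompressorNet:
    """Parameters of the 64-H-64 compressor.

    ``w_in[i, j]`` connects input i to hidden j; ``w_rec[i, j]`` connects
    the previous hidden state i to hidden j (``None`` when the context is
    disabled); ``w_out[j, k]`` connects hidden j to output k.
    """

    w_in: np.ndarray
    b_hidden: np.ndarray
    w_rec: np.ndarray | None
    w_out: np.ndarray
    b_out: np.ndarray

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[1]

    @property
    def recurrent(self) -> bool:
        return self.w_rec is not None

    @property
    def shape(self) -> NetShape:
        return NetShape(self.n_hidden, self.recurrent)

    def flatten(self) -> np.ndarray:
        """Parameters as one flat vector in the documented order."""
        parts = [self.w_in.ravel(), self.b_hidden]
        if self.w_rec is not None:
            parts.append(self.w_rec.ravel())
        parts.extend([self.w_out.ravel(), self.b_out])
        return np.concatenate(parts)

    @classmethod
    def from_flat(cls, params, shape: NetShape) -> "CompressorNet":
        """Inverse of :meth:`flatten` for the given layout."""
        p = np.asarray(params, dtype=np.float64)
        if p.ndim != 1 or p.size != shape.n_params:
            raise ValueError(
                f"expected {shape.n_params} parameters, got {p.size}"
            )
        h = shape.n_hidden
        pos = 0

        def take(n):
            nonlocal pos
            out = p[pos:pos + n]
            pos += n
            return out

        w_in = take(N_INPUT * h).reshape(N_INPUT, h)
        b_hidden = take(h)
        w_rec = take(h * h).reshape(h, h) if shape.recurrent else None
        w_out = take(h * N_INPUT).reshape(h, N_INPUT)
        b_out = take(N_INPUT)
        return cls(w_in=w_in.copy(), b_hidden=b_hidden.copy(),
                   w_rec=None if w_rec is None else w_rec.copy(),
                   w_out=w_out.copy(), b_out=b_out.copy())


def init_network(n_hidden: int, recurrent: bool = True,
                 seed: int = 0) -> CompressorNet:
    """Random network with all parameters i.i.d. uniform on [−0.5, 0.5]."""
    if n_hidden not in ALLOWED_HIDDEN:
        raise ValueError(
            f"n_hidden must be one of {ALLOWED_HIDDEN}, got {n_hidden}"
        )
    shape = NetShape(n_hidden, recurrent)
    rng = np.random.default_rng(seed)
    params = rng.uniform(-0.5, 0.5, size=shape.n_params)
    return CompressorNet.from_flat(params, shape)


def forward(net: CompressorNet, input64,
            prev_hidden=None) -> tuple[np.ndarray, np.ndarray]:
    """One block through the network.

    Returns ``(hidden, output)`` with ``hidden = σ(w_inᵀx + w_rec·h_prev
    + b)`` and ``output = σ(w_outᵀhidden + b_out)``.  ``prev_hidden``
    defaults to the zero vector and is ignored when recurrence is off.
    """
    x = np.asarray(input64, dtype=np.float64)
    if x.shape != (N_INPUT,):
        raise ValueError(f"input must have length {N_INPUT}")
    pre = x @ net.w_in + net.b_hidden
    if net.recurrent:
        if prev_hidden is None:
            prev_hidden = np.zeros(net.n_hidden)
        hp = np.asarray(prev_hidden, dtype=np.float64)
        if hp.shape != (net.n_hidden,):
            raise ValueError("prev_hidden length must equal n_hidden")
        pre = pre + hp @ net.w_rec
    hidden = sigmoid(pre)
    output = sigmoid(hidden @ net.w_out + net.b_out)
    return hidden, output


def encode_blocks(net: CompressorNet, blocks: BlockSet | np.ndarray) -> np.ndarray:
    """Hidden codes for every block, in raster order.

    With recurrence on, the hidden state is threaded across consecutive
    blocks (zero state before the first).  Without recurrence all blocks
    are encoded independently in one batched pass.
    """
    x = blocks.blocks if isinstance(blocks, BlockSet) else np.asarray(blocks)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != N_INPUT:
        raise ValueError(f"blocks must be (n, {N_INPUT})")
    if x.shape[0] == 0:
        raise ValueError("empty block set")
    if not net.recurrent:
        return sigmoid(x @ net.w_in + net.b_hidden)
    h = np.zeros(net.n_hidden)
    codes = np.empty((x.shape[0], net.n_hidden))
    for i in range(x.shape[0]):
        h = sigmoid(x[i] @ net.w_in + h @ net.w_rec + net.b_hidden)
        codes[i] = h
    return codes


def decode_hidden(net: CompressorNet, hidden_vectors,
                  template: BlockSet | None = None) -> BlockSet | np.ndarray:
    """Reconstruct 64-vectors from hidden codes through the output layer.

    When ``template`` is given (the encode-side :class:`BlockSet`), its
    grid metadata is copied onto the result so it can be untiled.
    """
    hv = np.asarray(hidden_vectors, dtype=np.float64)
    if hv.ndim != 2 or hv.shape[1] != net.n_hidden:
        raise ValueError(f"hidden vectors must be (n, {net.n_hidden})")
    out = sigmoid(hv @ net.w_out + net.b_out)
    if template is None:
        return out
    if hv.shape[0] != template.blocks.shape[0]:
        raise ValueError("hidden vector count differs from template blocks")
    return BlockSet(
        blocks=out,
        grid_dims=template.grid_dims,
        source_dims=template.source_dims,
        block_size=template.block_size,
    )


def reconstruction_fitness(params, blocks, shape: NetShape) -> float:
    """Mean squared autoencoding error — the objective GenPSO minimizes.

    ``blocks`` is an (n, 64) array (or BlockSet) of normalized block
    vectors; ``params`` a flat genome for ``shape``.
    """
    x = blocks.blocks if isinstance(blocks, BlockSet) else np.asarray(blocks)
    net = CompressorNet.from_flat(params, shape)
    codes = encode_blocks(net, x)
    recon = decode_hidden(net, codes)
    d = recon - x
    return float(np.mean(d * d))
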