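"""End-to-end GenPSOWVQ codec: train, compress, decompress, evaluate.

Pipeline (encode side): 2-D wavelet transform → per-plane normalization to
[0, 1] → 8×8 block tiling → hidden code per block through the compressor
network → nearest-codeword index per code.  The stream carries the indices
plus a self-contained header (decoder weights, codebook, normalization
constants).  Decode runs the same chain backwards and clips/rounds to the
8-bit pixel lattice.

Training fits both the network weights and the codebook on a corpus of
images with the GenPSO optimizer: first the network against the block
autoencoding error, then the codebook against the VQ distortion of the
resulting hidden codes.  A model can be trained once per dataset and
applied to many images, or trained on the input image itself
(``train([image], …)``) for a fully self-contained single-image codec.

The normalization constants are per image and per plane (approximation
plane by its own min/max, detail planes symmetrically by their largest
magnitude) and travel in the stream, so compression adapts to each
image's coefficient range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .bitstream import Bitstream, PlanePayload
from .genpso import GenPSOConfig, genpso_optimize
from .metrics import QualityReport, quality_report
from .network import (CompressorNet, NetShape, encode_blocks,
                      reconstruction_fitness, sigmoid)
from .vq import Codebook, build_codebook, vq_encode
from .wavelet_blocks import (BlockSet, SubbandSet, denormalize, dwt2, idwt2,
                             normalize, tile_blocks, untile_blocks)

__all__ = ["CodecConfig", "CodecModel", "train", "compress", "decompress",
           "evaluate"]

MODEL_MAGIC = "GWM1"


@dataclass
class CodecConfig:
    """Everything that defines a codec training run.

    ``n_hidden`` (the bottleneck width) and ``K`` (codebook size) set the
    rate: each 8×8 block costs ``log2(K)`` bits.  ``net_opt`` / ``cb_opt``
    override the GenPSO settings for the two training stages; when left
    ``None``, defaults sized for small training corpora are used and
    seeded from ``seed``.
    """

    family: str = "haar"
    level: int = 1
    n_hidden: int = 16
    K: int = 256
    recurrent: bool = True
    block_size: int = 8
    seed: int = 0
    net_opt: GenPSOConfig | None = None
    cb_opt: GenPSOConfig | None = None

    def resolved_net_opt(self) -> GenPSOConfig:
        if self.net_opt is not None:
            return self.net_opt
        return GenPSOConfig(population_size=50, ga_max_gen=40,
                            stagnation_window=20, pso_max_iter=600,
                            seed=self.seed)

    def resolved_cb_opt(self) -> GenPSOConfig:
        if self.cb_opt is not None:
            return self.cb_opt
        return GenPSOConfig(population_size=50, ga_max_gen=40,
                            stagnation_window=20, pso_max_iter=200,
                            seed=self.seed + 1)

    @classmethod
    def for_small_corpus(cls, n_hidden: int = 16, K: int = 64,
                         seed: int = 0) -> "CodecConfig":
        """Training recipe sized for small corpora (≲16 images of 64×64).

        Uses the plain feed-forward variant (no recurrent context) so the
        whole evaluation budget goes into the block autoencoder, with a
        short GA warm-up handing a still-diverse population to a long PSO
        refinement.  Runs in well under a minute per model on one CPU.
        """
        return cls(
            n_hidden=n_hidden, K=K, recurrent=False, seed=seed,
            net_opt=GenPSOConfig(population_size=50, ga_max_gen=60,
                                 stagnation_window=30, pso_max_iter=2000,
                                 velocity_clamp=0.2, seed=seed),
            cb_opt=GenPSOConfig(population_size=50, ga_max_gen=60,
                                stagnation_window=30, pso_max_iter=300,
                                velocity_clamp=0.2, seed=seed + 1),
        )


@dataclass
class CodecModel:
    """A trained codec: compressor network + codebook + transform config."""

    net: CompressorNet
    codebook: Codebook
    family: str
    level: int
    block_size: int
    seed: int

    def __post_init__(self):
        if self.codebook.dim != self.net.n_hidden:
            raise ValueError("codebook dimension must equal n_hidden")

    # -- model file (.gwm): JSON, float32 precision ---------------------

    def save(self, path) -> None:
        def f32(a):
            return None if a is None else \
                np.asarray(a, dtype=np.float32).astype(float).ravel().tolist()

        doc = {
            "magic": MODEL_MAGIC,
            "family": self.family,
            "level": self.level,
            "block_size": self.block_size,
            "seed": self.seed,
            "n_hidden": self.net.n_hidden,
            "recurrent": self.net.recurrent,
            "K": self.codebook.K,
            "w_in": f32(self.net.w_in),
            "b_hidden": f32(self.net.b_hidden),
            "w_rec": f32(self.net.w_rec),
            "w_out": f32(self.net.w_out),
            "b_out": f32(self.net.b_out),
            "codebook": f32(self.codebook.codewords),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "CodecModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("magic") != MODEL_MAGIC:
            raise ValueError(f"{path} is not a {MODEL_MAGIC} model file")
        h = doc["n_hidden"]

        def arr(name, shape):
            v = doc[name]
            return None if v is None else \
                np.asarray(v, dtype=np.float64).reshape(shape)

        net = CompressorNet(
            w_in=arr("w_in", (64, h)),
            b_hidden=arr("b_hidden", (h,)),
            w_rec=arr("w_rec", (h, h)) if doc["recurrent"] else None,
            w_out=arr("w_out", (h, 64)),
            b_out=arr("b_out", (64,)),
        )
        cb = Codebook(codewords=arr("codebook", (doc["K"], h)))
        return cls(net=net, codebook=cb, family=doc["family"],
                   level=doc["level"], block_size=doc["block_size"],
                   seed=doc["seed"])


def _check_image(image) -> np.ndarray:
    a = np.asarray(image)
    if a.ndim != 2:
        raise ValueError("expected a 2-D greyscale image")
    if min(a.shape) < 8:
        raise ValueError("image dimensions must be at least 8")
    return a.astype(np.float64)


def _plane_range(plane: np.ndarray, is_approx: bool) -> tuple[float, float]:
    """Normalization range: approximation by min/max, details by ±max|c|."""
    if is_approx:
        lo, hi = float(plane.min()), float(plane.max())
        if hi <= lo:
            hi = lo + 1.0
        return lo, hi
    m = float(np.abs(plane).max())
    if m <= 0.0:
        m = 1.0
    return -m, m


def _image_planes(image: np.ndarray, config_or_model) -> list[np.ndarray]:
    sub = dwt2(image, level=config_or_model.level,
               family=config_or_model.family)
    return sub.planes()


def train(images, config: CodecConfig | None = None) -> CodecModel:
    """Fit network and codebook on a corpus of greyscale images.

    Deterministic given ``config.seed``.  A constant corpus (zero pixel
    variance) still yields a model but triggers a warning, since there is
    nothing informative to fit.
    """
    if config is None:
        config = CodecConfig()
    imgs = [_check_image(im) for im in images]
    if not imgs:
        raise ValueError("training requires at least one image")
    if all(float(im.std()) == 0.0 for im in imgs):
        warnings.warn("training corpus is constant; model will be trivial",
                      stacklevel=2)

    pooled = []
    for im in imgs:
        for i, plane in enumerate(_image_planes(im, config)):
            lo, hi = _plane_range(plane, is_approx=(i == 0))
            pooled.append(tile_blocks(normalize(plane, lo, hi),
                                      config.block_size).blocks)
    blocks = np.vstack(pooled)

    shape = NetShape(config.n_hidden, config.recurrent)
    net_cfg = replace(config.resolved_net_opt(),
                      node_shape=shape.node_slices())
    result = genpso_optimize(
        lambda p: reconstruction_fitness(p, blocks, shape),
        shape.n_params, net_cfg)
    net = CompressorNet.from_flat(result.best_position, shape)

    codes = encode_blocks(net, blocks)
    codebook = build_codebook(codes, config.K, config.resolved_cb_opt())
    return CodecModel(net=net, codebook=codebook, family=config.family,
                      level=config.level, block_size=config.block_size,
                      seed=config.seed)


def compress(image, model: CodecModel) -> Bitstream:
    """Encode one image to a self-contained bitstream."""
    a = _check_image(image)
    planes = _image_planes(a, model)
    payloads: list[PlanePayload] = []
    for i, plane in enumerate(planes):
        lo, hi = _plane_range(plane, is_approx=(i == 0))
        bs = tile_blocks(normalize(plane, lo, hi), model.block_size)
        codes = encode_blocks(model.net, bs)
        stream = vq_encode(codes, model.codebook)
        payloads.append(PlanePayload(plane_dims=bs.source_dims,
                                     grid_dims=bs.grid_dims,
                                     lo=lo, hi=hi,
                                     indices=stream.indices))
    return Bitstream(
        height=a.shape[0], width=a.shape[1],
        family=model.family, level=model.level,
        n_hidden=model.net.n_hidden, K=model.codebook.K,
        recurrent=model.net.recurrent,
        w_out=model.net.w_out, b_out=model.net.b_out,
        codebook=model.codebook.codewords, planes=payloads)


def decompress(stream: Bitstream | bytes) -> np.ndarray:
    """Reconstruct the image from a stream (bytes or parsed).

    Uses only information inside the stream.  The result is clipped to
    [0, 255] and rounded half-up to uint8.
    """
    if isinstance(stream, (bytes, bytearray)):
        bs = Bitstream.from_bytes(stream)
    else:
        # canonicalize through serialization so reconstruction is defined
        # by the stream's quantized header, not in-memory precision
        bs = Bitstream.from_bytes(stream.to_bytes())
    expected = 1 + 3 * bs.level
    if len(bs.planes) != expected:
        raise ValueError(
            f"stream has {len(bs.planes)} planes, expected {expected} "
            f"for a level-{bs.level} transform")
    rec_planes = []
    for p in bs.planes:
        hv = bs.codebook[p.indices]
        out64 = sigmoid(hv @ bs.w_out + bs.b_out)
        block = BlockSet(blocks=out64, grid_dims=p.grid_dims,
                         source_dims=p.plane_dims)
        rec_planes.append(denormalize(untile_blocks(block), p.lo, p.hi))
    details = [tuple(rec_planes[1 + 3 * k: 4 + 3 * k])
               for k in range(bs.level)]
    sub = SubbandSet(approximation=rec_planes[0], details=details,
                     level=bs.level, family=bs.family,
                     original_dims=(bs.height, bs.width))
    plane = idwt2(sub)
    return np.clip(np.floor(plane + 0.5), 0, 255).astype(np.uint8)


def evaluate(image, model: CodecModel) -> QualityReport:
    """Compress, serialize, decompress, and score the round trip.

    The reconstruction is decoded from the serialized bytes, so the
    report reflects exactly what a receiver of the stream would see, and
    ``cr_percent`` uses the true serialized bit count.
    """
    a = _check_image(image)
    data = compress(a, model).to_bytes()
    recon = decompress(data)
    return quality_report(a, recon, 8 * len(data))
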